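"""Sample x taxon community matrices and the operations around them.

The :class:`CommunityMatrix` is the universal currency of the pipeline: a
validated, non-negative sample x taxon table that is either raw sequence
counts (``kind="counts"``) or relative abundances (``kind="relative"``,
every sample row summing to one).  On disk, OTU tables follow the common
convention of taxa as rows and samples as columns; in memory everything is
sample x taxon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-9

COALESCED_SOURCES = frozenset({"OC", "RC"})
VALID_SOURCES = frozenset({"R", "S", "Rx", "Sx", "OC", "RC"})

METADATA_COLUMNS = ["sample_id", "source", "river_parts", "sea_parts", "replicate", "day"]


class CommunityMatrixError(ValueError):
    """Raised when a table violates a CommunityMatrix invariant."""


@dataclass(frozen=True)
class CommunityMatrix:
    """A validated sample x taxon abundance table.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with one column per taxon id.
    kind:
        ``"counts"`` (non-negative integers) or ``"relative"`` (rows sum
        to one).
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise CommunityMatrixError(f"unknown kind {self.kind!r}")
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CommunityMatrixError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise CommunityMatrixError(f"duplicate taxon ids: {dups}")
        values = df.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise CommunityMatrixError(
                f"non-finite value at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        if values.size and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise CommunityMatrixError(
                f"negative value {values[r, c]} at sample {df.index[r]!r}, "
                f"taxon {df.columns[c]!r}"
            )
        if self.kind == "counts":
            if values.size and not np.allclose(values, np.round(values)):
                r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
                raise CommunityMatrixError(
                    f"non-integral count {values[r, c]} at sample {df.index[r]!r}, "
                    f"taxon {df.columns[c]!r}"
                )
        else:
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _ROW_SUM_TOL
            if bad.any():
                s = df.index[np.argmax(bad)]
                raise CommunityMatrixError(
                    f"relative matrix row {s!r} sums to {sums[np.argmax(bad)]!r}, not 1"
                )

    # -- basic views ----------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select_taxa(self, taxa: Iterable) -> "CommunityMatrix":
        """Subset to the given taxa.

        Counts subsets keep raw counts; relative subsets are renormalised so
        rows still sum to one (a sample with zero abundance over the selected
        taxa is an error).
        """
        taxa = [t for t in taxa if t in self.data.columns]
        sub = self.data.loc[:, taxa]
        if self.kind == "relative":
            sums = sub.sum(axis=1)
            if (sums <= 0).any():
                bad = sums.index[sums <= 0][0]
                raise CommunityMatrixError(
                    f"sample {bad!r} has zero abundance over the selected taxa"
                )
            sub = sub.div(sums, axis=0)
        return CommunityMatrix(sub, self.kind)

    def select_samples(self, samples: Iterable) -> "CommunityMatrix":
        return CommunityMatrix(self.data.loc[list(samples)], self.kind)


def to_relative(cm: CommunityMatrix) -> CommunityMatrix:
    """Convert counts to relative abundances (row-normalise).

    Raises on any all-zero sample, naming it.
    """
    if cm.kind == "relative":
        return cm
    totals = cm.data.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise CommunityMatrixError(f"sample {bad!r} has zero total count")
    return CommunityMatrix(cm.data.div(totals, axis=0), "relative")


def rarefy(cm: CommunityMatrix, depth: int, seed: int) -> CommunityMatrix:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning.  Deterministic for a fixed seed.
    """
    if cm.kind != "counts":
        raise CommunityMatrixError("rarefaction requires a counts matrix")
    if depth <= 0:
        raise CommunityMatrixError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    counts = cm.data.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(cm.sample_ids, keep) if not k]
    if dropped:
        msg = f"rarefy: dropping {len(dropped)} sample(s) below depth {depth}: {dropped}"
        logger.warning(msg)
        warnings.warn(msg)
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    row = 0
    for i in range(counts.shape[0]):
        if not keep[i]:
            continue
        if totals[i] == depth:
            out[row] = counts[i]
        else:
            out[row] = rng.multivariate_hypergeometric(counts[i], depth)
        row += 1
    df = pd.DataFrame(out, index=[s for s, k in zip(cm.sample_ids, keep) if k],
                      columns=cm.data.columns)
    return CommunityMatrix(df, "counts")


def prevalence(cm: CommunityMatrix) -> pd.Series:
    """Fraction of samples in which each taxon is present (value > 0)."""
    return (cm.data > 0).mean(axis=0)


def prevalence_filter(cm: CommunityMatrix, threshold: float = 0.10) -> list:
    """Taxa present in strictly more than ``threshold`` of the samples.

    The boundary is exclusive: a taxon found in exactly 10% of samples is
    *not* retained at threshold 0.10.
    """
    if not 0 <= threshold < 1:
        raise CommunityMatrixError(f"threshold must be in [0, 1), got {threshold}")
    prev = prevalence(cm)
    return [t for t in cm.taxon_ids if prev[t] > threshold]


def shared_and_unique_taxa(
    groups: Mapping[str, CommunityMatrix],
) -> tuple[set, dict[str, set]]:
    """Global shared taxa and per-group unique taxa.

    shared = taxa with nonzero abundance in every group; unique(g) = taxa
    nonzero only in group g.
    """
    if len(groups) < 2:
        raise CommunityMatrixError("need at least two groups")
    present = {
        name: set(cm.data.columns[(cm.data > 0).any(axis=0)]) for name, cm in groups.items()
    }
    names = list(present)
    shared = set.intersection(*present.values())
    unique = {}
    for g in names:
        others = set().union(*(present[o] for o in names if o != g))
        unique[g] = present[g] - others
    return shared, unique


# -- disk formats -------------------------------------------------------

def read_community_table(
    path, orientation: str = "taxa_as_rows", kind: str | None = None
) -> CommunityMatrix:
    """Read a tab-separated OTU table.

    ``orientation="taxa_as_rows"`` (the usual dialect, header cell
    ``taxon_id``, one column per sample) or ``"samples_as_rows"``.  ``kind``
    is inferred when omitted: an all-integral table is counts, otherwise it
    must be row-normalised relative abundances.
    """
    if orientation not in ("taxa_as_rows", "samples_as_rows"):
        raise CommunityMatrixError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise CommunityMatrixError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "taxa_as_rows":
        df = df.T
    if kind is None:
        vals = df.to_numpy()
        kind = "counts" if np.allclose(vals, np.round(vals)) else "relative"
    if kind == "counts":
        df = df.round().astype(np.int64)
    df.index.name = "sample_id"
    df.columns.name = None
    return CommunityMatrix(df, kind)


def write_community_table(cm: CommunityMatrix, path, orientation: str = "taxa_as_rows") -> None:
    """Write a CommunityMatrix as TSV; round-trips with the reader."""
    df = cm.data
    if orientation == "taxa_as_rows":
        out = df.T
        out.index.name = "taxon_id"
    elif orientation == "samples_as_rows":
        out = df.copy()
        out.index.name = "sample_id"
    else:
        raise CommunityMatrixError(f"unknown orientation {orientation!r}")
    out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class ExperimentDesign:
    """Per-sample treatment labels for a coalescence microcosm experiment.

    Columns: sample_id, source (R/S/Rx/Sx/OC/RC), river_parts, sea_parts
    (blank for non-coalesced samples), replicate, day.
    """

    table: pd.DataFrame = field()

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in METADATA_COLUMNS if c not in t.columns]
        if missing:
            raise CommunityMatrixError(f"metadata missing column(s): {missing}")
        bad = set(t["source"]) - VALID_SOURCES
        if bad:
            raise CommunityMatrixError(f"unknown source label(s): {sorted(bad)}")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise CommunityMatrixError(f"duplicate sample ids in metadata: {dups}")
        coalesced = t["source"].isin(COALESCED_SOURCES)
        ratios = t.loc[coalesced, ["river_parts", "sea_parts"]]
        if ratios.isna().any().any():
            raise CommunityMatrixError("OC/RC samples must carry a river:sea ratio")
        if ((ratios.fillna(0).sum(axis=1)) <= 0).any():
            raise CommunityMatrixError("OC/RC ratio parts must not both be zero")

    def samples(
        self, source: str | None = None, day: int | None = None,
        ratio: tuple[int, int] | None = None,
    ) -> list:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if source is not None:
            mask &= t["source"] == source
        if day is not None:
            mask &= t["day"] == day
        if ratio is not None:
            mask &= (t["river_parts"] == ratio[0]) & (t["sea_parts"] == ratio[1])
        return t.loc[mask, "sample_id"].tolist()

    def replicate_of(self, sample_id) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise CommunityMatrixError(f"sample {sample_id!r} not in metadata")
        return str(row["replicate"].iloc[0])


def read_metadata(path) -> ExperimentDesign:
    t = pd.read_csv(path, sep="\t", dtype={"replicate": str})
    return ExperimentDesign(t)


def write_metadata(design: ExperimentDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)
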