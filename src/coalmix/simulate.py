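"""Synthetic serial-transfer coalescence experiments with ground truth.

The generator emulates a two-habitat microcosm study: a river (R) and a
brackish sea (S) parent community with partially overlapping taxon pools
are mixed at volumetric river:sea ratios, either once (OC) or repeatedly
(RC, 20% volume replaced with fresh parent mixture every transfer), over a
16-day incubation sampled every 4 days.  Environmental-coalescence controls
(Rx, Sx) expose each unmixed parent to the blended 1:1 medium, declining a
planted set of environment-sensitive taxa.

Abundances follow a latent compositional model: replicate-level Dirichlet
variation around a habitat base composition, planted taxon-taxon
correlation via shared lognormal latent factors (positive blocks move
together; negative pairs move in anti-phase), per-taxon multiplicative
fitness in mixed medium, and multinomial read sampling at a fixed
sequencing depth.  Every draw flows from a single seed.

Defaults encode the study conditions: 5 replicates, ratios 1:1 / 1:2 / 2:1,
20% exchange every 4 days over 16 days, sequencing depth 5000 (the order of
the study's rarefaction depth), and a sea-fitness advantage in mixed medium
(salt-sensitive river specialists decline while sea taxa can exploit the
river-derived nitrogen supply).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .community import (
    CommunityMatrix,
    CommunityMatrixError,
    ExperimentDesign,
    write_community_table,
    write_metadata,
)

REPLICATE_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic coalescence experiment.

    The defaults are the emulated study conditions; taxon-pool sizes are a
    desk-scale stand-in for the study's several hundred OTUs.
    """

    n_taxa_river: int = 120          # taxa in the river pool (incl. shared)
    n_taxa_sea: int = 120            # taxa in the sea pool (incl. shared)
    n_shared: int = 60               # taxa common to both pools
    base_concentration: float = 0.3  # Dirichlet concentration for base compositions
    replicate_concentration: float = 600.0  # Dirichlet precision of replicate variation
    n_replicates: int = 5
    mixing_ratios: tuple = ((1, 1), (1, 2), (2, 1))  # (river_parts, sea_parts)
    days: tuple = (0, 4, 8, 12, 16)
    exchange_fraction: float = 0.2
    n_positive_block: int = 10       # shared taxa coupled by a common latent factor
    positive_loading: float = 0.5    # lognormal sigma of the shared factor
    n_negative_pairs: int = 5        # shared-taxon pairs forced into anti-phase
    negative_loading: float = 1.0    # see-saw sharpness of the anti-phase pairs
    n_env_sensitive: int = 10        # habitat specialists filtered by mixed medium
    env_decline: float = 0.05        # multiplier on sensitive taxa in Rx/Sx
    fitness_river: float = 0.2       # river specialists' growth factor in pure sea medium
    fitness_sea: float = 1.8         # sea specialists' growth factor in pure river medium
    sequencing_depth: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_taxa_river, self.n_taxa_sea):
            raise CommunityMatrixError(
                "n_shared exceeds the smaller taxon pool (field: n_shared)"
            )
        if not 0 < self.exchange_fraction < 1:
            raise CommunityMatrixError(
                f"exchange_fraction must be in (0, 1), got {self.exchange_fraction} "
                "(field: exchange_fraction)"
            )
        if not 0 < self.env_decline <= 1:
            raise CommunityMatrixError(
                f"env_decline must be in (0, 1], got {self.env_decline} "
                "(field: env_decline)"
            )
        if self.n_replicates < 1 or self.n_replicates > len(REPLICATE_LABELS):
            raise CommunityMatrixError(
                f"n_replicates out of range (field: n_replicates): {self.n_replicates}"
            )
        if self.sequencing_depth < 1:
            raise CommunityMatrixError(
                f"sequencing_depth must be positive (field: sequencing_depth)"
            )
        for r, s in self.mixing_ratios:
            if r < 0 or s < 0 or r + s <= 0:
                raise CommunityMatrixError(
                    f"invalid mixing ratio {(r, s)} (field: mixing_ratios)"
                )

    @property
    def replicate_labels(self) -> list[str]:
        return list(REPLICATE_LABELS[: self.n_replicates])

    @property
    def n_cultures(self) -> int:
        """Total incubated cultures: community microcosms plus the paired
        per-replicate sterile media bottles (R_m, S_m)."""
        n_treatments = 4 + 2 * len(self.mixing_ratios)  # R, S, Rx, Sx, OC/RC x ratios
        return (n_treatments + 2) * self.n_replicates


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated experiment."""

    base_river: pd.Series
    base_sea: pd.Series
    replicate_river: pd.DataFrame   # replicate x taxon latent compositions
    replicate_sea: pd.DataFrame
    positive_block: list
    negative_pairs: list
    env_sensitive_river: list
    env_sensitive_sea: list
    expected_mixtures: dict        # "r:s" -> replicate x taxon DataFrame
    latent_by_sample: pd.DataFrame  # sample x taxon pre-multinomial compositions
    seed: int


@dataclass(frozen=True)
class SyntheticDataset:
    """Counts, design and truth for one simulated experiment."""

    counts: CommunityMatrix
    design: ExperimentDesign
    truth: SyntheticTruth
    spec: SyntheticSpec

    @property
    def n_cultures(self) -> int:
        return self.spec.n_cultures


# ---------------------------------------------------------------------------
# building blocks


def _taxon_ids(spec: SyntheticSpec) -> tuple[list, list, list]:
    shared = [f"OTU_SH{i:03d}" for i in range(spec.n_shared)]
    river_only = [f"OTU_R{i:03d}" for i in range(spec.n_taxa_river - spec.n_shared)]
    sea_only = [f"OTU_S{i:03d}" for i in range(spec.n_taxa_sea - spec.n_shared)]
    return river_only, shared, sea_only


def _apply_latent_factors(
    latent: np.ndarray,
    pos_idx: np.ndarray,
    neg_pairs_idx: Sequence[tuple[int, int]],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One observation's composition: shared-factor perturbation + renorm.

    Positive-block members ride a common lognormal factor; each negative
    pair trades a conserved total share via a Beta(b, b) see-saw with
    b = 1/(1 + negative_loading).
    """
    x = latent.copy()
    if pos_idx.size:
        g = rng.lognormal(0.0, spec.positive_loading)
        x[pos_idx] *= g
    beta_shape = 1.0 / (1.0 + spec.negative_loading)
    for u, v in neg_pairs_idx:
        total_uv = x[u] + x[v]
        b = rng.beta(beta_shape, beta_shape)
        x[u], x[v] = total_uv * b, total_uv * (1.0 - b)
    total = x.sum()
    if total <= 0:
        raise CommunityMatrixError("latent composition collapsed to zero")
    return x / total


def _observe(latent: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    return rng.multinomial(depth, latent / latent.sum())


def generate_parents(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> SyntheticTruth:
    """Draw base and replicate-level parent compositions plus planted truth.

    River and sea bases are Dirichlet draws over their habitat pools
    (sharing ``n_shared`` taxa); replicate compositions are Dirichlet
    resamples around each base.  The positive block and negative pairs are
    the most abundant shared taxa (visible across all samples); the
    environment-sensitive sets are the most abundant habitat specialists.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    river_only, shared, sea_only = _taxon_ids(spec)
    taxa = river_only + shared + sea_only

    def _base(pool: list[str]) -> pd.Series:
        comp = rng.dirichlet(np.full(len(pool), spec.base_concentration))
        return pd.Series(comp, index=pool).reindex(taxa, fill_value=0.0)

    base_r = _base(river_only + shared)
    base_s = _base(shared + sea_only)

    def _replicates(base: pd.Series, pool: list[str]) -> pd.DataFrame:
        alpha = base[pool].to_numpy() * spec.replicate_concentration
        alpha = np.maximum(alpha, 1e-6)  # Dirichlet needs strictly positive alphas
        rows = {
            lab: pd.Series(rng.dirichlet(alpha), index=pool).reindex(taxa, fill_value=0.0)
            for lab in spec.replicate_labels
        }
        return pd.DataFrame(rows).T

    rep_r = _replicates(base_r, river_only + shared)
    rep_s = _replicates(base_s, shared + sea_only)

    # planted structure: blocks among abundant shared taxa, sensitivity among
    # abundant habitat specialists
    shared_rank = (base_r[shared] + base_s[shared]).sort_values(ascending=False).index
    pos_block = list(shared_rank[: spec.n_positive_block])
    pair_pool = list(shared_rank[spec.n_positive_block:
                                 spec.n_positive_block + 2 * spec.n_negative_pairs])
    neg_pairs = [tuple(pair_pool[2 * i: 2 * i + 2]) for i in range(len(pair_pool) // 2)]
    sens_r = list(base_r[river_only].sort_values(ascending=False).index[: spec.n_env_sensitive])
    sens_s = list(base_s[sea_only].sort_values(ascending=False).index[: spec.n_env_sensitive])

    mixtures = {}
    for r, s in spec.mixing_ratios:
        mixtures[f"{r}:{s}"] = (r * rep_r + s * rep_s) / (r + s)

    return SyntheticTruth(
        base_river=base_r,
        base_sea=base_s,
        replicate_river=rep_r,
        replicate_sea=rep_s,
        positive_block=pos_block,
        negative_pairs=neg_pairs,
        env_sensitive_river=sens_r,
        env_sensitive_sea=sens_s,
        expected_mixtures=mixtures,
        latent_by_sample=pd.DataFrame(columns=taxa),
        seed=spec.seed,
    )


def apply_environmental_filter(
    latent: pd.Series,
    sensitive: Sequence,
    multiplier: float,
) -> pd.Series:
    """Decline sensitive taxa by ``multiplier`` and renormalise.

    Models environmental filtering by the blended medium: the latent
    abundance of every sensitive taxon is multiplied by a factor in (0, 1].
    """
    if not 0 < multiplier <= 1:
        raise CommunityMatrixError(f"decline multiplier must be in (0, 1], got {multiplier}")
    out = latent.astype(float).copy()
    idx = [t for t in sensitive if t in out.index]
    out[idx] *= multiplier
    total = out.sum()
    if total <= 0:
        raise CommunityMatrixError("environmental filter removed the whole community")
    return out / total


def _growth_vector(spec: SyntheticSpec, taxa: list, ratio: tuple[int, int]) -> np.ndarray:
    """Per-taxon growth factor per 4-day step in an r:s mixed medium.

    Habitat specialists have fitness 1 in their own medium and
    ``fitness_river`` / ``fitness_sea`` in the foreign one; the effective
    factor blends log-fitness by the foreign-medium volume fraction.
    Shared taxa are generalists (factor 1).
    """
    r, s = ratio
    w_sea = s / (r + s)  # fraction of sea medium
    g = np.ones(len(taxa))
    for i, t in enumerate(taxa):
        if t.startswith("OTU_R"):
            g[i] = spec.fitness_river ** w_sea
        elif t.startswith("OTU_S"):
            g[i] = spec.fitness_sea ** (1.0 - w_sea)
    return g


def simulate_coalescence(
    spec: SyntheticSpec,
    truth: SyntheticTruth,
    mode: str,
    ratio: tuple[int, int],
    replicate: str,
) -> dict[int, pd.Series]:
    """Latent composition trajectory of one coalesced microcosm.

    Day 0 is the ratio-weighted convex mixture of the paired parent
    replicates.  Each 4-day step applies (a) the growth factors for the
    mixed medium, then (b) the exchange: OC replaces 20% of the volume with
    cell-free medium (pure dilution, a no-op on proportions), RC replaces it
    with the fresh parent mixture at the treatment ratio.
    """
    if mode not in ("OC", "RC"):
        raise CommunityMatrixError(f"unknown coalescence mode {mode!r}")
    r, s = ratio
    if r < 0 or s < 0 or r + s <= 0:
        raise CommunityMatrixError(f"invalid mixing ratio {ratio!r}")
    taxa = list(truth.base_river.index)
    pr = truth.replicate_river.loc[replicate].to_numpy(dtype=float)
    ps = truth.replicate_sea.loc[replicate].to_numpy(dtype=float)
    mixture = (r * pr + s * ps) / (r + s)
    growth = _growth_vector(spec, taxa, ratio)
    f = spec.exchange_fraction

    days = sorted(spec.days)
    out: dict[int, pd.Series] = {days[0]: pd.Series(mixture, index=taxa)}
    latent = mixture.copy()
    for day in days[1:]:
        # one growth + exchange step per sampled 4-day interval
        latent = latent * growth
        latent = latent / latent.sum()
        if mode == "RC":
            latent = (1 - f) * latent + f * mixture
            latent = latent / latent.sum()
        out[day] = pd.Series(latent, index=taxa)
    return out


def generate_experiment(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Simulate the full experiment and return counts + design + truth.

    Sample ids look like ``R_A_d16`` or ``RC_1-2_C_d8``.  Every treatment is
    observed at every sampled day; the day-16 slice reproduces the study
    layout (2 parents + 2 environmental controls + 2 coalescence modes x 3
    ratios, 5 replicates each).
    """
    if spec is None:
        spec = SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    truth = generate_parents(spec, rng)
    taxa = list(truth.base_river.index)
    river_only, shared, sea_only = _taxon_ids(spec)
    pos_idx = np.array([taxa.index(t) for t in truth.positive_block], dtype=int)
    neg_idx = [(taxa.index(u), taxa.index(v)) for u, v in truth.negative_pairs]

    rows, meta, latents = {}, [], {}

    def _emit(sample_id, source, ratio, rep, day, latent: pd.Series) -> None:
        realized = _apply_latent_factors(
            latent.to_numpy(dtype=float), pos_idx, neg_idx, spec, rng
        )
        rows[sample_id] = _observe(realized, spec.sequencing_depth, rng)
        latents[sample_id] = realized
        meta.append(
            {
                "sample_id": sample_id,
                "source": source,
                "river_parts": ratio[0] if ratio else np.nan,
                "sea_parts": ratio[1] if ratio else np.nan,
                "replicate": rep,
                "day": day,
            }
        )

    days = sorted(spec.days)
    for rep in spec.replicate_labels:
        lat_r = truth.replicate_river.loc[rep]
        lat_s = truth.replicate_sea.loc[rep]
        lat_rx = apply_environmental_filter(lat_r, truth.env_sensitive_river, spec.env_decline)
        lat_sx = apply_environmental_filter(lat_s, truth.env_sensitive_sea, spec.env_decline)
        for day in days:
            _emit(f"R_{rep}_d{day}", "R", None, rep, day, lat_r)
            _emit(f"S_{rep}_d{day}", "S", None, rep, day, lat_s)
            # the mixed medium needs time to act: day 0 is the unfiltered inoculum
            _emit(f"Rx_{rep}_d{day}", "Rx", None, rep, day, lat_r if day == days[0] else lat_rx)
            _emit(f"Sx_{rep}_d{day}", "Sx", None, rep, day, lat_s if day == days[0] else lat_sx)
        for mode in ("OC", "RC"):
            for ratio in spec.mixing_ratios:
                traj = simulate_coalescence(spec, truth, mode, ratio, rep)
                tag = f"{mode}_{ratio[0]}-{ratio[1]}_{rep}"
                for day in days:
                    _emit(f"{tag}_d{day}", mode, ratio, rep, day, traj[day])

    counts = CommunityMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=taxa).astype(np.int64),
        "counts",
    )
    design = ExperimentDesign(pd.DataFrame(meta))
    truth = SyntheticTruth(
        base_river=truth.base_river,
        base_sea=truth.base_sea,
        replicate_river=truth.replicate_river,
        replicate_sea=truth.replicate_sea,
        positive_block=truth.positive_block,
        negative_pairs=truth.negative_pairs,
        env_sensitive_river=truth.env_sensitive_river,
        env_sensitive_sea=truth.env_sensitive_sea,
        expected_mixtures=truth.expected_mixtures,
        latent_by_sample=pd.DataFrame.from_dict(latents, orient="index", columns=taxa),
        seed=spec.seed,
    )
    return SyntheticDataset(counts=counts, design=design, truth=truth, spec=spec)


def emit_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write otu_table.tsv, metadata.tsv and truth.json; re-readable by the
    community-table reader."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": out / "otu_table.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
    }
    write_community_table(dataset.counts, paths["otu_table"])
    write_metadata(dataset.design, paths["metadata"])
    t = dataset.truth
    payload = {
        "seed": int(t.seed),
        "n_cultures": dataset.n_cultures,
        "positive_block": list(t.positive_block),
        "negative_pairs": [list(p) for p in t.negative_pairs],
        "env_sensitive_river": list(t.env_sensitive_river),
        "env_sensitive_sea": list(t.env_sensitive_sea),
        "base_river": {k: round(float(v), 8) for k, v in t.base_river.items()},
        "base_sea": {k: round(float(v), 8) for k, v in t.base_sea.items()},
        "expected_mixtures": {
            ratio: {rep: {k: round(float(v), 8) for k, v in row.items()}
                    for rep, row in df.iterrows()}
            for ratio, df in t.expected_mixtures.items()
        },
        "latent_by_sample": {
            s: [round(float(v), 6) for v in row]
            for s, row in zip(t.latent_by_sample.index, t.latent_by_sample.to_numpy())
        },
        "taxon_ids": list(t.latent_by_sample.columns),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh)
    return paths


# ---------------------------------------------------------------------------
# focused generators for calibration studies


def simulate_independent_community(
    n_samples: int,
    n_taxa: int,
    seed: int,
    concentration_sigma: float = 1.5,
) -> CommunityMatrix:
    """Compositions with no planted taxon-taxon coupling.

    Each sample is an independent Dirichlet draw with a fixed, uneven
    concentration vector (log-normal spread ``concentration_sigma``),
    mimicking the uneven abundance distribution of real communities.  The
    only residual dependence is the compositional closure itself, which the
    unevenness keeps small.
    """
    rng = np.random.default_rng(seed)
    alpha = rng.lognormal(0.0, concentration_sigma, size=n_taxa)
    comps = rng.dirichlet(alpha, size=n_samples)
    df = pd.DataFrame(
        comps,
        index=[f"SA{i:03d}" for i in range(n_samples)],
        columns=[f"OTU{j:03d}" for j in range(n_taxa)],
    )
    return CommunityMatrix(df, "relative")


def simulate_correlated_community(
    n_samples: int,
    n_taxa: int,
    seed: int,
    block: Sequence[int] = (),
    positive_loading: float = 0.8,
    negative_pairs: Sequence[tuple[int, int]] = (),
    negative_loading: float = 0.8,
    concentration_sigma: float = 1.0,
) -> CommunityMatrix:
    """Compositions with planted correlation structure.

    ``block`` members share a per-sample lognormal factor (positive mutual
    correlation).  Each pair in ``negative_pairs`` is driven in anti-phase
    by a see-saw: the pair's total share is conserved and reallocated by a
    per-sample Beta(b, b) split with b = 1/(1 + negative_loading), so the
    members trade abundance without perturbing the rest of the composition
    (a two-species competitive exclusion caricature).

    Taxa are ordered by expected abundance (index 0 most abundant), so
    planted structure on low indices involves the community's dominant
    members.

    Draw order is nested — base compositions, then the block factor, then
    one see-saw stream per pair — so enlarging ``negative_pairs`` extends
    the same realisation instead of resampling it (paired sweeps).
    """
    rng = np.random.default_rng(seed)
    alpha = np.sort(rng.lognormal(0.0, concentration_sigma, size=n_taxa))[::-1]
    block = np.asarray(list(block), dtype=int)
    beta_shape = 1.0 / (1.0 + negative_loading)
    comps = rng.dirichlet(alpha, size=n_samples)
    if block.size:
        g = rng.lognormal(0.0, positive_loading, size=n_samples)
        comps[:, block] *= g[:, None]
    for u, v in negative_pairs:
        total = comps[:, u] + comps[:, v]
        b = rng.beta(beta_shape, beta_shape, size=n_samples)
        comps[:, u], comps[:, v] = total * b, total * (1.0 - b)
    comps /= comps.sum(axis=1, keepdims=True)
    df = pd.DataFrame(
        comps,
        index=[f"SA{i:03d}" for i in range(n_samples)],
        columns=[f"OTU{j:03d}" for j in range(n_taxa)],
    )
    return CommunityMatrix(df, "relative")
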