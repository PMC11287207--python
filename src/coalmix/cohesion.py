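"""Community cohesion and the negative:positive stability ratio.

Cohesion measures how connected each observed community is.  The chain is:

1. pairwise product-moment correlations between taxa across samples
   (relative abundances of the *non-rarefied* table);
2. a taxon-shuffle null model: each taxon's abundance vector is permuted
   across samples many times and the average correlation with every other
   taxon is recorded — this captures the correlation expected from the
   abundance distributions alone;
3. corrected correlation = observed - null expectation;
4. per-taxon connectedness = mean of the strictly positive (resp. strictly
   negative) corrected correlations with all other taxa;
5. per-sample cohesion = abundance-weighted sum of connectedness;
6. stability ratio = |negative cohesion / positive cohesion|.  Values < 1
   indicate facilitation/synchrony dominance (positive-feedback loops,
   lower stability); values > 1 indicate competition dominance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityMatrix, CommunityMatrixError, prevalence_filter, to_relative
from .diffabund import bh_adjust

logger = logging.getLogger(__name__)


def _standardize_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores; zero-variance columns become all-zero (flagged)."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    z = (x - mu) / sd_safe
    z[:, constant] = 0.0
    return z, constant


def pairwise_correlations(cm: CommunityMatrix) -> pd.DataFrame:
    """Product-moment correlation of every taxon pair across samples.

    Requires >= 3 samples and a relative-abundance matrix.  Pairs involving
    a zero-variance taxon are set to 0; the diagonal is set to 0 (excluded
    from all downstream means).
    """
    if cm.kind != "relative":
        raise CommunityMatrixError("correlations are computed on relative abundances")
    if cm.n_samples < 3:
        raise CommunityMatrixError(
            f"need at least 3 samples for correlations, got {cm.n_samples}"
        )
    x = cm.values()
    z, constant = _standardize_columns(x)
    n = x.shape[0]
    r = (z.T @ z) / n
    np.clip(r, -1.0, 1.0, out=r)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 0.0)
    if constant.any():
        logger.warning(
            "pairwise_correlations: %d zero-variance taxa set to correlation 0",
            int(constant.sum()),
        )
    return pd.DataFrame(r, index=cm.taxon_ids, columns=cm.taxon_ids)


def null_expected_correlations(
    cm: CommunityMatrix, n_iter: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Taxon-shuffle null expectation of every pairwise correlation.

    For each ordered pair (i, j), taxon j's abundance vector is permuted
    across samples ``n_iter`` times and its correlation with the unpermuted
    taxon i is averaged; the matrix is then symmetrised by averaging the
    (i, j) and (j, i) estimates.  Deterministic for a fixed seed.
    """
    if n_iter < 1:
        raise CommunityMatrixError(f"n_iter must be >= 1, got {n_iter}")
    if cm.kind != "relative":
        raise CommunityMatrixError("correlations are computed on relative abundances")
    if cm.n_samples < 3:
        raise CommunityMatrixError(
            f"need at least 3 samples for correlations, got {cm.n_samples}"
        )
    rng = np.random.default_rng(seed)
    x = cm.values()
    n, t = x.shape
    z_obs, constant = _standardize_columns(x)
    acc = np.zeros((t, t))
    for _ in range(n_iter):
        shuffled = rng.permuted(x, axis=0)  # independent permutation per taxon
        z_perm, _ = _standardize_columns(shuffled)
        # entry (i, j): corr(observed taxon i, permuted taxon j)
        acc += (z_obs.T @ z_perm) / n
    mean_null = acc / n_iter
    null = 0.5 * (mean_null + mean_null.T)
    null[constant, :] = 0.0
    null[:, constant] = 0.0
    np.fill_diagonal(null, 0.0)
    return pd.DataFrame(null, index=cm.taxon_ids, columns=cm.taxon_ids)


@dataclass(frozen=True)
class CorrelationSet:
    """Observed, null-expected and corrected pairwise correlations."""

    observed: pd.DataFrame
    null_expected: pd.DataFrame
    n_null_iterations: int
    seed: int

    def __post_init__(self) -> None:
        if not self.observed.index.equals(self.null_expected.index):
            raise CommunityMatrixError("observed/null taxon sets differ")
        for name, m in (("observed", self.observed), ("null_expected", self.null_expected)):
            v = m.to_numpy()
            if not np.allclose(v, v.T, atol=1e-12):
                raise CommunityMatrixError(f"{name} correlation matrix is not symmetric")

    @property
    def taxon_ids(self) -> list:
        return list(self.observed.index)

    @property
    def corrected(self) -> pd.DataFrame:
        c = self.observed - self.null_expected
        np.fill_diagonal(c.values, 0.0)
        return c


def correlation_set(
    cm: CommunityMatrix, n_iter: int = 200, seed: int = 0
) -> CorrelationSet:
    """Convenience: observed + null correlations for one matrix."""
    return CorrelationSet(
        observed=pairwise_correlations(cm),
        null_expected=null_expected_correlations(cm, n_iter=n_iter, seed=seed),
        n_null_iterations=n_iter,
        seed=seed,
    )


def connectedness(cs: CorrelationSet) -> pd.DataFrame:
    """Per-taxon mean positive and mean negative corrected correlation.

    ``connectedness_pos`` is the mean over strictly positive corrected
    correlations with the other taxa (0 when there are none);
    ``connectedness_neg`` the mean over strictly negative ones (<= 0).
    """
    c = cs.corrected.to_numpy().copy()
    t = c.shape[0]
    if t < 2:
        raise CommunityMatrixError("connectedness needs at least two taxa")
    np.fill_diagonal(c, 0.0)
    pos_mask = c > 0
    neg_mask = c < 0
    with np.errstate(invalid="ignore"):
        pos = np.where(pos_mask.any(axis=1),
                       np.where(pos_mask, c, 0.0).sum(axis=1)
                       / np.maximum(pos_mask.sum(axis=1), 1), 0.0)
        neg = np.where(neg_mask.any(axis=1),
                       np.where(neg_mask, c, 0.0).sum(axis=1)
                       / np.maximum(neg_mask.sum(axis=1), 1), 0.0)
    return pd.DataFrame(
        {"connectedness_pos": pos, "connectedness_neg": neg}, index=cs.taxon_ids
    )


def cohesion(cm: CommunityMatrix, conn: pd.DataFrame) -> pd.DataFrame:
    """Per-sample positive and negative cohesion.

    cohesion_pos(s) = sum_j a_sj * connectedness_pos(j) with a_sj the
    relative abundance of taxon j in sample s; analogously for negative.
    """
    rel = to_relative(cm)
    missing = [t for t in rel.taxon_ids if t not in conn.index]
    if missing:
        raise CommunityMatrixError(
            f"{len(missing)} taxa lack connectedness values, e.g. {missing[:3]}"
        )
    conn_aligned = conn.loc[rel.taxon_ids]
    a = rel.values()
    pos = a @ conn_aligned["connectedness_pos"].to_numpy()
    neg = a @ conn_aligned["connectedness_neg"].to_numpy()
    return pd.DataFrame(
        {"cohesion_pos": pos, "cohesion_neg": neg}, index=rel.sample_ids
    )


def stability_ratio(coh: pd.DataFrame) -> pd.Series:
    """|cohesion_neg / cohesion_pos| per sample.

    Samples with cohesion_pos == 0 get NaN (undefined, logged) rather than
    an exception or infinity.
    """
    pos = coh["cohesion_pos"].to_numpy(dtype=float)
    neg = coh["cohesion_neg"].to_numpy(dtype=float)
    undefined = pos == 0
    if undefined.any():
        bad = list(coh.index[undefined])
        logger.warning("stability_ratio undefined (cohesion_pos = 0) for %s", bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(neg / pos)
    ratio[undefined] = np.nan
    return pd.Series(ratio, index=coh.index, name="stability")


@dataclass(frozen=True)
class CohesionResult:
    """Connectedness, cohesion and stability for one community table."""

    connectedness: pd.DataFrame  # per taxon: connectedness_pos / connectedness_neg
    cohesion: pd.DataFrame       # per sample: cohesion_pos / cohesion_neg
    stability: pd.Series         # per sample, NaN where undefined
    n_null_iterations: int
    seed: int
    prevalence_threshold: float


def cohesion_pipeline(
    cm: CommunityMatrix,
    prevalence_threshold: float = 0.10,
    n_iter: int = 200,
    seed: int = 0,
    samples_for_connectedness: Sequence | None = None,
) -> CohesionResult:
    """Full chain: prevalence filter -> correlations -> null -> cohesion.

    ``cm`` should be the non-rarefied counts table (the null-corrected
    correlations are estimated on its relative abundances).  By default
    connectedness is estimated over all samples jointly;
    ``samples_for_connectedness`` restricts the estimation set (cohesion and
    stability are still reported for every sample).
    """
    rel_all = to_relative(cm)
    keep = prevalence_filter(rel_all, prevalence_threshold)
    if len(keep) < 2:
        raise CommunityMatrixError(
            f"only {len(keep)} taxa pass the {prevalence_threshold:.0%} prevalence filter"
        )
    rel = rel_all.select_taxa(keep)
    est = rel if samples_for_connectedness is None else rel.select_samples(
        samples_for_connectedness
    )
    cs = correlation_set(est, n_iter=n_iter, seed=seed)
    conn = connectedness(cs)
    coh = cohesion(rel, conn)
    stab = stability_ratio(coh)
    return CohesionResult(
        connectedness=conn,
        cohesion=coh,
        stability=stab,
        n_null_iterations=n_iter,
        seed=seed,
        prevalence_threshold=prevalence_threshold,
    )


def compare_stability(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise Wilcoxon rank-sum tests on per-sample stabilities.

    NaN (undefined) stabilities are dropped per group; groups left with
    fewer than two values are excluded with a warning.  P-values are
    Benjamini-Hochberg adjusted across the pairs.
    """
    clean: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        v = np.asarray(list(vals), dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 2:
            msg = f"compare_stability: group {name!r} has <2 defined values, excluded"
            logger.warning(msg)
            warnings.warn(msg)
            continue
        clean[name] = v
    names = list(clean)
    if len(names) < 2:
        raise CommunityMatrixError("need at least two usable groups")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = stats.mannwhitneyu(clean[a], clean[b], alternative="two-sided")
            rows.append({"group_a": a, "group_b": b,
                         "statistic": float(res.statistic), "p_raw": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].tolist())
    out["significant"] = out["p_adj"] < alpha
    return out
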