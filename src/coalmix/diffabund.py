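"""Permutation differential abundance, the environmental screen, and
biotic-response classification.

The per-taxon test is a transparent two-sided label-permutation test on the
difference of group means of relative abundances, with the +1-corrected
p-value p = (1 + #{|stat*| >= |stat|}) / (1 + n_perm) and Benjamini-Hochberg
FDR control across taxa.  The downstream logic consumes only a direction
(increase/decrease) and an FDR-adjusted significance call per taxon, so any
per-taxon two-group test with those outputs can be plugged in.

The environmental screen isolates the biotic component of coalescence: a
taxon is carried forward only if it is present in both the parent community
and its environmentally treated counterpart AND did not significantly
decrease under the changed environment alone.  Abundance shifts of the
screened taxa in coalesced communities are then attributed to community
interactions rather than environmental filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import CommunityMatrix, CommunityMatrixError, prevalence, to_relative

logger = logging.getLogger(__name__)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        bad = p[~((p >= 0) & (p <= 1))][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass(frozen=True)
class DiffAbundResult:
    """Per-taxon permutation-test results for one two-group comparison."""

    table: pd.DataFrame  # index taxon_id; statistic, p_raw, p_adj, direction, prevalence
    n_permutations: int
    seed: int
    alpha: float

    @property
    def increased(self) -> list:
        return list(self.table.index[self.table["direction"] == "increase"])

    @property
    def decreased(self) -> list:
        return list(self.table.index[self.table["direction"] == "decrease"])


def _aligned_relative(
    a: CommunityMatrix, b: CommunityMatrix, taxa: Sequence | None = None
) -> tuple[np.ndarray, np.ndarray, list]:
    """Relative abundances of both groups over the union taxon set.

    When ``taxa`` is given, columns are restricted to it *after* the
    whole-community normalisation, so values stay proportions of the full
    community rather than of the subset.
    """
    ra, rb = to_relative(a), to_relative(b)
    if taxa is None:
        taxa = sorted(set(ra.taxon_ids) | set(rb.taxon_ids))
    else:
        taxa = list(taxa)
    xa = ra.data.reindex(columns=taxa, fill_value=0.0).to_numpy(dtype=float)
    xb = rb.data.reindex(columns=taxa, fill_value=0.0).to_numpy(dtype=float)
    return xa, xb, taxa


def permutation_da_test(
    group_a: CommunityMatrix,
    group_b: CommunityMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    taxa: Sequence | None = None,
) -> DiffAbundResult:
    """Two-sided permutation test of mean(group_b) - mean(group_a) per taxon.

    Labels are randomly reassigned ``n_perm`` times; the p-value uses the
    +1 correction, so the smallest attainable p_raw is 1/(n_perm + 1).
    ``direction`` is the sign of the observed statistic for taxa with
    p_adj < alpha, else "none".  ``taxa`` restricts the tested columns
    (keeping whole-community proportions); FDR control is applied across the
    tested taxa only.
    """
    if group_a.n_samples < 2 or group_b.n_samples < 2:
        raise CommunityMatrixError("each group needs at least two samples")
    if n_perm < 1:
        raise CommunityMatrixError(f"n_perm must be >= 1, got {n_perm}")
    xa, xb, taxa = _aligned_relative(group_a, group_b, taxa=taxa)
    na, nb = xa.shape[0], xb.shape[0]
    pooled = np.vstack([xa, xb])
    observed = xb.mean(axis=0) - xa.mean(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(taxa), dtype=np.int64)
    abs_obs = np.abs(observed)
    for _ in range(n_perm):
        idx = rng.permutation(na + nb)
        pa = pooled[idx[:na]]
        pb = pooled[idx[na:]]
        stat = pb.mean(axis=0) - pa.mean(axis=0)
        # strict exceedance: permutations that merely recreate the observed
        # split (always possible at small n) do not count against a complete
        # separation, so such a taxon attains the minimum p of 1/(n_perm+1)
        exceed += np.abs(stat) > abs_obs + 1e-12
    p_raw = (1 + exceed) / (1 + n_perm)
    p_raw[abs_obs <= 1e-15] = 1.0  # no observed difference -> never significant
    p_adj = np.asarray(bh_adjust(p_raw))

    prev = ((pooled > 0).sum(axis=0)) / (na + nb)
    direction = np.where(
        p_adj < alpha, np.where(observed > 0, "increase", "decrease"), "none"
    )
    direction = np.where((p_adj < alpha) & (observed == 0), "none", direction)
    table = pd.DataFrame(
        {
            "statistic": observed,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": direction,
            "prevalence": prev,
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    return DiffAbundResult(table=table, n_permutations=n_perm, seed=seed, alpha=alpha)


def environmental_screen(
    parent: CommunityMatrix,
    env_treated: CommunityMatrix,
    da: DiffAbundResult,
    alpha: float = 0.05,
) -> list:
    """Taxa unaffected by environmental coalescence.

    Retains taxa that are present (nonzero in at least one sample) in both
    the parent community and the environmentally treated community, and that
    show no significant decrease (p_adj < alpha with a negative statistic,
    parent -> treated) under the changed environment.  Significant increases
    are retained.
    """
    present_parent = set(parent.data.columns[(parent.data > 0).any(axis=0)])
    present_env = set(env_treated.data.columns[(env_treated.data > 0).any(axis=0)])
    candidates = present_parent & present_env
    t = da.table
    sig_decrease = set(
        t.index[(t["p_adj"] < alpha) & (t["statistic"] < 0)]
    )
    retained = sorted(candidates - sig_decrease)
    logger.info(
        "environmental_screen: %d/%d taxa retained (%d significant decreases)",
        len(retained), len(candidates), len(sig_decrease & candidates),
    )
    return retained


def biotic_response(
    coalesced: CommunityMatrix,
    parent_reference: CommunityMatrix,
    screen: Sequence,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    prevalence_threshold: float = 0.10,
) -> DiffAbundResult:
    """Significant abundance shifts of screened taxa after coalescence.

    Restricts to screened taxa with prevalence strictly above
    ``prevalence_threshold`` across the combined sample set, then runs the
    permutation test of coalesced vs parent reference.  The ``increased``
    and ``decreased`` properties of the result give the response sets.
    """
    screen = list(screen)
    if not screen:
        raise CommunityMatrixError("environmental screen retained no taxa")
    taxa = sorted(set(screen) & set(coalesced.taxon_ids) & set(parent_reference.taxon_ids))
    combined = pd.concat(
        [
            coalesced.data.reindex(columns=taxa, fill_value=0.0),
            parent_reference.data.reindex(columns=taxa, fill_value=0.0),
        ]
    )
    prev = (combined > 0).mean(axis=0)
    analysed = [t for t in taxa if prev[t] > prevalence_threshold]
    if not analysed:
        raise CommunityMatrixError(
            "no screened taxa pass the prevalence filter for the response test"
        )
    return permutation_da_test(
        parent_reference,
        coalesced,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        taxa=analysed,
    )


def aggregate_response(
    groups: Mapping[str, CommunityMatrix],
    response_set: Sequence,
) -> tuple[pd.DataFrame, dict]:
    """Total relative abundance of a response set per sample, compared
    across groups with a Kruskal-Wallis test.

    Returns (per-sample totals with a ``group`` column, test summary dict).
    An empty response set yields all-zero totals and a flagged, untested
    summary.
    """
    response_set = list(response_set)
    rows = []
    for name, cm in groups.items():
        rel = to_relative(cm)
        cols = [t for t in response_set if t in rel.data.columns]
        totals = rel.data[cols].sum(axis=1) if cols else pd.Series(0.0, index=rel.data.index)
        for s, v in totals.items():
            rows.append({"sample_id": s, "group": name, "total_relative_abundance": float(v)})
    out = pd.DataFrame(rows)
    if not response_set:
        logger.warning("aggregate_response: empty response set, no test performed")
        return out, {"tested": False, "reason": "empty response set"}
    samples = [g["total_relative_abundance"].to_numpy() for _, g in out.groupby("group")]
    if len(samples) < 2:
        return out, {"tested": False, "reason": "fewer than two groups"}
    flat = out["total_relative_abundance"].to_numpy()
    if np.allclose(flat, flat[0]):
        # all observations identical: no rank separation possible
        return out, {"tested": True, "statistic": 0.0, "p_value": 1.0, "degenerate": True}
    res = stats.kruskal(*samples)
    return out, {
        "tested": True,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "degenerate": False,
    }
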