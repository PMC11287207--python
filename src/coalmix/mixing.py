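"""Conservative mixing model for community coalescence.

Under the conservative (null) model, mixing two communities at a volumetric
ratio r:s produces the ratio-weighted convex combination of the parent
compositions — no selection, no interactions.  Comparing observed coalesced
communities with this expectation via Bray-Curtis similarity quantifies how
predictable the coalescence outcome was, and paired comparisons of
observed- vs expected-similarity to each parent classify the outcome as
convergence toward, or divergence from, a parent community.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis

from .community import CommunityMatrixError


def _align(x: pd.Series, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    taxa = sorted(set(x.index) | set(y.index))
    return (
        x.reindex(taxa, fill_value=0.0).to_numpy(dtype=float),
        y.reindex(taxa, fill_value=0.0).to_numpy(dtype=float),
    )


def expected_community(
    parent_r: pd.Series, parent_s: pd.Series, ratio: tuple[float, float]
) -> pd.Series:
    """Expected coalesced composition E = (r*R + s*S) / (r + s).

    Parents are relative compositions over possibly different taxon sets;
    the expectation lives on the union (absent taxa are zero) and sums to 1.
    """
    r, s = ratio
    if r < 0 or s < 0 or r + s <= 0:
        raise CommunityMatrixError(f"invalid mixing ratio {ratio!r}")
    taxa = sorted(set(parent_r.index) | set(parent_s.index))
    xr = parent_r.reindex(taxa, fill_value=0.0).astype(float)
    xs = parent_s.reindex(taxa, fill_value=0.0).astype(float)
    return (r * xr + s * xs) / (r + s)


def bray_curtis_similarity(x: pd.Series, y: pd.Series) -> float:
    """1 - Bray-Curtis dissimilarity on the union taxon set (in [0, 1])."""
    xv, yv = _align(x, y)
    if xv.sum() == 0 and yv.sum() == 0:
        raise CommunityMatrixError("Bray-Curtis undefined for two all-zero compositions")
    return float(1.0 - braycurtis(xv, yv))


@dataclass(frozen=True)
class MixingExpectation:
    """Observed vs expected coalesced compositions for one treatment."""

    treatment: str
    ratio: tuple[int, int]
    expected: pd.DataFrame   # replicate x taxon, relative
    observed: pd.DataFrame   # replicate x taxon, relative
    similarity_obs_exp: pd.Series          # per replicate
    similarity_to_parent: pd.DataFrame     # per replicate: obs_R, exp_R, obs_S, exp_S

    @property
    def replicates(self) -> list:
        return list(self.expected.index)


def build_expectation(
    parent_r: pd.DataFrame,
    parent_s: pd.DataFrame,
    observed: pd.DataFrame,
    ratio: tuple[int, int],
    treatment: str = "",
) -> MixingExpectation:
    """Pair parent and coalesced replicates by label and build expectations.

    All three frames are replicate x taxon relative compositions.  The
    expected community for replicate k is mixed from parent replicates with
    the same label k, mirroring the replicate-paired medium/community
    exchange of the experimental design.
    """
    reps = sorted(observed.index)
    orphans = (
        [k for k in reps if k not in parent_r.index]
        + [k for k in reps if k not in parent_s.index]
    )
    if orphans:
        raise CommunityMatrixError(
            f"replicates without parent counterparts: {sorted(set(orphans))}"
        )
    taxa = sorted(
        set(parent_r.columns) | set(parent_s.columns) | set(observed.columns)
    )
    exp_rows, obs_rows, sims, parent_sims = {}, {}, {}, []
    for k in reps:
        pr = parent_r.loc[k].reindex(taxa, fill_value=0.0)
        ps = parent_s.loc[k].reindex(taxa, fill_value=0.0)
        ob = observed.loc[k].reindex(taxa, fill_value=0.0)
        ex = expected_community(pr, ps, ratio)
        exp_rows[k], obs_rows[k] = ex, ob
        sims[k] = bray_curtis_similarity(ob, ex)
        parent_sims.append(
            {
                "replicate": k,
                "obs_R": bray_curtis_similarity(ob, pr),
                "exp_R": bray_curtis_similarity(ex, pr),
                "obs_S": bray_curtis_similarity(ob, ps),
                "exp_S": bray_curtis_similarity(ex, ps),
            }
        )
    return MixingExpectation(
        treatment=treatment,
        ratio=tuple(ratio),
        expected=pd.DataFrame(exp_rows).T,
        observed=pd.DataFrame(obs_rows).T,
        similarity_obs_exp=pd.Series(sims, name="similarity_obs_exp"),
        similarity_to_parent=pd.DataFrame(parent_sims).set_index("replicate"),
    )


def deviation_test(similarities: Sequence[float]) -> dict:
    """One-sample t-test of the deviations (1 - similarity) against zero.

    A non-significant result means the observed communities do not deviate
    detectably from the mixing-model expectation (predictable coalescence).
    When every similarity equals 1 exactly the statistic is 0 and p is 1.
    """
    dev = 1.0 - np.asarray(list(similarities), dtype=float)
    if dev.size < 2:
        raise CommunityMatrixError("deviation test needs >= 2 replicates")
    if np.allclose(dev, 0.0):
        return {"statistic": 0.0, "p_value": 1.0, "mean_deviation": 0.0}
    res = stats.ttest_1samp(dev, popmean=0.0)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_deviation": float(dev.mean()),
    }


def predictability(
    expectations: Mapping[str, MixingExpectation], alpha: float = 0.05
) -> dict:
    """Predictability summary across coalescence treatments.

    Per treatment: mean and sd of the observed-vs-expected Bray-Curtis
    similarities plus the one-sample deviation test.  Across treatments:
    one-way ANOVA on the similarities and Tukey's HSD for all pairs.
    Higher mean similarity = more predictable coalescence outcome.
    """
    per_treatment = {}
    groups, names = [], []
    for name, me in expectations.items():
        sims = me.similarity_obs_exp.to_numpy(dtype=float)
        test = deviation_test(sims)
        per_treatment[name] = {
            "mean_similarity": float(sims.mean()),
            "sd_similarity": float(sims.std(ddof=1)) if sims.size > 1 else 0.0,
            "deviation_statistic": test["statistic"],
            "deviation_p": test["p_value"],
            "predictable": test["p_value"] >= alpha,
            "n_replicates": int(sims.size),
        }
        groups.append(sims)
        names.append(name)
    summary: dict = {"per_treatment": per_treatment}
    if len(groups) >= 2:
        flat = np.concatenate(groups)
        if np.allclose(flat, flat.mean()):
            summary["anova"] = {"F": 0.0, "p_value": 1.0}
        else:
            f = stats.f_oneway(*groups)
            summary["anova"] = {"F": float(f.statistic), "p_value": float(f.pvalue)}
            hsd = stats.tukey_hsd(*groups)
            pairs = []
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    pairs.append(
                        {
                            "group_a": names[i],
                            "group_b": names[j],
                            "p_value": float(hsd.pvalue[i, j]),
                            "significant": bool(hsd.pvalue[i, j] < alpha),
                        }
                    )
            summary["tukey_pairs"] = pairs
    return summary


def parent_convergence(me: MixingExpectation, alpha: float = 0.05) -> pd.DataFrame:
    """Paired comparison of similarity-to-parent: observed vs expected.

    For each parent, a paired t-test of BC(observed, parent) against
    BC(expected, parent) across replicates.  Significantly lower observed
    similarity = "divergence" (the coalesced community moved further from
    that parent than the mixing model predicts); significantly higher =
    "convergence"; otherwise "none".
    """
    rows = []
    sp = me.similarity_to_parent
    for parent in ("R", "S"):
        obs = sp[f"obs_{parent}"].to_numpy(dtype=float)
        exp = sp[f"exp_{parent}"].to_numpy(dtype=float)
        if obs.size < 2:
            raise CommunityMatrixError("parent_convergence needs >= 2 replicates")
        diff = obs - exp
        if np.allclose(diff, 0.0):
            statistic, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(obs, exp)
            statistic, p = float(res.statistic), float(res.pvalue)
        if p < alpha and diff.mean() > 0:
            classification = "convergence"
        elif p < alpha and diff.mean() < 0:
            classification = "divergence"
        else:
            classification = "none"
        rows.append(
            {
                "parent": parent,
                "mean_obs_similarity": float(obs.mean()),
                "mean_exp_similarity": float(exp.mean()),
                "statistic": statistic,
                "p_value": p,
                "classification": classification,
            }
        )
    return pd.DataFrame(rows).set_index("parent")


def expectation_table(expectations: Mapping[str, MixingExpectation]) -> pd.DataFrame:
    """Flat per-replicate table (treatment, ratio, similarities) for export."""
    rows = []
    for name, me in expectations.items():
        sp = me.similarity_to_parent
        for k in me.replicates:
            rows.append(
                {
                    "treatment": name,
                    "ratio": f"{me.ratio[0]}:{me.ratio[1]}",
                    "replicate": k,
                    "similarity_obs_exp": float(me.similarity_obs_exp[k]),
                    "sim_obs_R": float(sp.loc[k, "obs_R"]),
                    "sim_exp_R": float(sp.loc[k, "exp_R"]),
                    "sim_obs_S": float(sp.loc[k, "obs_S"]),
                    "sim_exp_S": float(sp.loc[k, "exp_S"]),
                }
            )
    return pd.DataFrame(rows)
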