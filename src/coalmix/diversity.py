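"""Alpha diversity and group comparisons.

Richness is the number of taxa with nonzero abundance, Shannon diversity
uses the natural logarithm, and the inverse Simpson index is 1 / sum(p^2).
Group differences are tested per metric with a one-way ANOVA followed by
Tukey's HSD over all pairs, summarised with a compact letter display
(groups sharing a letter are not significantly different).
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity.alpha import inv_simpson, shannon, sobs

from .community import CommunityMatrix, CommunityMatrixError

logger = logging.getLogger(__name__)

METRICS = ("richness", "shannon", "inverse_simpson")


def alpha_diversity(cm: CommunityMatrix) -> pd.DataFrame:
    """Per-sample richness, Shannon (natural log) and inverse Simpson.

    Empty samples get NaN diversity values (undefined) with richness 0.
    """
    rows = []
    for sample_id, row in cm.data.iterrows():
        v = row.to_numpy(dtype=float)
        if v.sum() <= 0:
            logger.warning("alpha_diversity: sample %r is empty, metrics undefined", sample_id)
            rows.append({"sample_id": sample_id, "richness": 0,
                         "shannon": np.nan, "inverse_simpson": np.nan})
            continue
        rows.append(
            {
                "sample_id": sample_id,
                "richness": int(sobs(v > 0)),
                "shannon": float(shannon(v)),
                "inverse_simpson": float(inv_simpson(v)),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _compact_letters(names: Sequence[str], sig_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Greedy compact letter display: groups share a letter iff no
    significant difference separates them within that letter's clique."""
    letters: list[set[str]] = []
    for name in names:
        placed = False
        for clique in letters:
            if all((min(name, o), max(name, o)) not in sig_pairs for o in clique):
                clique.add(name)
                placed = True
        if not placed:
            letters.append({name})
    # drop cliques fully contained in another
    keep = [c for i, c in enumerate(letters)
            if not any(c < o for j, o in enumerate(letters) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for letter, clique in zip(alphabet, keep):
        for name in clique:
            out[name] += letter
    return out


def compare_alpha(
    groups: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD per metric across labelled groups.

    ``groups`` maps group name to a per-sample metrics frame (as returned by
    :func:`alpha_diversity`).  Groups with fewer than two usable samples are
    excluded with a warning.  Returns one row per metric with the F
    statistic, p-value and per-group compact significance letters.
    """
    rows = []
    for metric in METRICS:
        clean: dict[str, np.ndarray] = {}
        for name, table in groups.items():
            v = table[metric].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            if v.size < 2:
                msg = f"compare_alpha: group {name!r} degenerate for {metric}, excluded"
                logger.warning(msg)
                warnings.warn(msg)
                continue
            clean[name] = v
        names = list(clean)
        if len(names) < 2:
            raise CommunityMatrixError(f"fewer than two usable groups for {metric}")
        values = list(clean.values())
        flat = np.concatenate(values)
        if np.allclose(flat, flat.mean()):
            f_stat, p = 0.0, 1.0
            sig_pairs: set[tuple[str, str]] = set()
        else:
            res = stats.f_oneway(*values)
            f_stat, p = float(res.statistic), float(res.pvalue)
            hsd = stats.tukey_hsd(*values)
            sig_pairs = {
                (min(names[i], names[j]), max(names[i], names[j]))
                for i in range(len(names))
                for j in range(i + 1, len(names))
                if hsd.pvalue[i, j] < alpha
            }
        letters = _compact_letters(names, sig_pairs)
        rows.append(
            {
                "metric": metric,
                "F": f_stat,
                "p_value": p,
                "significant": p < alpha,
                "letters": ";".join(f"{n}={letters[n]}" for n in names),
            }
        )
    return pd.DataFrame(rows).set_index("metric")
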