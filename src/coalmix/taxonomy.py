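"""Consensus taxonomy from multiple reference databases.

Long-read amplicon OTUs are typically classified against several reference
databases (e.g. an 18S, an LSU and an ITS database), and the classifications
rarely agree all the way down the rank ladder.  The consensus rule keeps a
rank-level name only while at least two of the three databases agree
("2 out of 3"), walking from the root rank downward and stopping at the
first rank without a two-way majority.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

DEFAULT_RANKS = (
    "domain",
    "supergroup",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

Lineage = Sequence[str]


def consensus_taxonomy(
    a: Lineage, b: Lineage, c: Lineage, ranks: Sequence[str] = DEFAULT_RANKS
) -> list[str]:
    """Majority-rule consensus of three ranked lineages.

    At each rank (root first) the name carried by at least two lineages is
    retained; the walk stops at the first rank where no name has two votes.
    Empty lineages simply never vote.  Matching is case-insensitive exact
    string equality; the returned names keep the casing of the first voter.
    Symmetric under permutation of the three inputs.
    """
    lineages = [list(lin) for lin in (a, b, c)]
    for lin in lineages:
        if len(lin) > len(ranks):
            raise ValueError(
                f"lineage of depth {len(lin)} exceeds the {len(ranks)}-rank ladder"
            )
    consensus: list[str] = []
    for depth in range(len(ranks)):
        votes: dict[str, str] = {}  # lowercase name -> first-seen casing
        counts: dict[str, int] = {}
        for lin in lineages:
            if depth < len(lin) and str(lin[depth]).strip():
                name = str(lin[depth]).strip()
                key = name.lower()
                votes.setdefault(key, name)
                counts[key] = counts.get(key, 0) + 1
        winners = [k for k, n in counts.items() if n >= 2]
        if not winners:
            break
        # two distinct names can never both reach 2 votes among 3 lineages
        consensus.append(votes[winners[0]])
    return consensus


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Per-OTU lineages from three reference databases plus their consensus."""

    taxon_id: str
    lineage_a: tuple[str, ...]
    lineage_b: tuple[str, ...]
    lineage_c: tuple[str, ...]
    consensus: tuple[str, ...]

    @classmethod
    def build(
        cls, taxon_id: str, a: Lineage, b: Lineage, c: Lineage,
        ranks: Sequence[str] = DEFAULT_RANKS,
    ) -> "TaxonomyAssignment":
        return cls(
            taxon_id=taxon_id,
            lineage_a=tuple(a),
            lineage_b=tuple(b),
            lineage_c=tuple(c),
            consensus=tuple(consensus_taxonomy(a, b, c, ranks)),
        )


def _split(s) -> list[str]:
    if pd.isna(s) or not str(s).strip():
        return []
    return [p.strip() for p in str(s).split(";") if p.strip()]


def read_taxonomy_table(path, ranks: Sequence[str] = DEFAULT_RANKS) -> list[TaxonomyAssignment]:
    """Read a TSV with columns taxon_id, lineage_a, lineage_b, lineage_c
    (semicolon-delimited lineages) and compute the consensus for each row."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    required = ["taxon_id", "lineage_a", "lineage_b", "lineage_c"]
    missing = [c for c in required if c not in t.columns]
    if missing:
        raise ValueError(f"taxonomy table missing column(s): {missing}")
    return [
        TaxonomyAssignment.build(
            row["taxon_id"], _split(row["lineage_a"]), _split(row["lineage_b"]),
            _split(row["lineage_c"]), ranks,
        )
        for _, row in t.iterrows()
    ]


def write_taxonomy_table(assignments: Sequence[TaxonomyAssignment], path) -> None:
    rows = [
        {
            "taxon_id": a.taxon_id,
            "lineage_a": ";".join(a.lineage_a),
            "lineage_b": ";".join(a.lineage_b),
            "lineage_c": ";".join(a.lineage_c),
            "consensus": ";".join(a.consensus),
        }
        for a in assignments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
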