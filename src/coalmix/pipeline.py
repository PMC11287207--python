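"""One-shot end-to-end analysis of a coalescence experiment.

Stage order follows the study's analysis chain: rarefy -> alpha diversity
-> cohesion/stability (on the *non-rarefied* table) -> environmental screen
(R vs Rx, S vs Sx) -> conservative mixing model + predictability -> biotic
response + aggregate response.  Every stage writes TSV/JSON outputs under
``out_dir/<stage>/`` and the run ends with a manifest recording parameters,
derived seeds and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import (
    CommunityMatrix,
    CommunityMatrixError,
    ExperimentDesign,
    read_community_table,
    read_metadata,
    rarefy,
    to_relative,
    write_community_table,
)
from .cohesion import cohesion_pipeline, compare_stability
from .diffabund import (
    aggregate_response,
    biotic_response,
    environmental_screen,
    permutation_da_test,
)
from .diversity import alpha_diversity, compare_alpha
from .mixing import (
    build_expectation,
    expectation_table,
    parent_convergence,
    predictability,
)
from .simulate import SyntheticSpec, emit_dataset, generate_experiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and knobs of the end-to-end run.

    Exactly one of (``otu_table`` + ``metadata``) or ``synthetic`` must be
    provided.
    """

    otu_table: str | None = None
    metadata: str | None = None
    synthetic: SyntheticSpec | None = None
    rarefaction_depth: int = 4752
    prevalence_threshold: float = 0.10
    alpha: float = 0.05
    n_perm: int = 999
    n_null_iter: int = 200
    seed: int = 0
    out_dir: str = "coalmix_results"
    parent_day: int | None = None  # parent snapshot for the mixing model; None = last day
    cohesion_on_rarefied: bool = False  # override flag; default follows the method

    def __post_init__(self) -> None:
        has_files = self.otu_table is not None and self.metadata is not None
        if has_files == (self.synthetic is not None):
            raise CommunityMatrixError(
                "provide either input paths (otu_table + metadata) or a synthetic spec"
            )
        if not 0 <= self.prevalence_threshold < 1:
            raise CommunityMatrixError("prevalence_threshold must be in [0, 1)")
        if not 0 < self.alpha < 1:
            raise CommunityMatrixError("alpha must be in (0, 1)")
        if self.rarefaction_depth <= 0 or self.n_perm < 1 or self.n_null_iter < 1:
            raise CommunityMatrixError("depth / n_perm / n_null_iter must be positive")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive per-stage seeds from the config seed (documented scheme:
    ``SeedSequence(seed).generate_state(n)``, folded below 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31 - 1)) for s in state]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _group_tables(cm: CommunityMatrix, design: ExperimentDesign, day: int):
    """Per-treatment day slices as CommunityMatrix, keyed by treatment tag."""
    out: dict[str, CommunityMatrix] = {}
    t = design.table
    day_rows = t[t["day"] == day]
    for (source, r, s), g in day_rows.groupby(
        ["source", "river_parts", "sea_parts"], dropna=False
    ):
        tag = source if pd.isna(r) else f"{source}_{int(r)}:{int(s)}"
        samples = [s_ for s_ in g["sample_id"] if s_ in cm.data.index]
        if samples:
            out[tag] = cm.select_samples(samples)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(
        ["simulate", "rarefy", "cohesion", "screen_R", "screen_S", "respond", "perm_extra"],
        _child_seeds(config.seed, 7),
    ))
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "parameters": {
            "rarefaction_depth": config.rarefaction_depth,
            "prevalence_threshold": config.prevalence_threshold,
            "alpha": config.alpha,
            "n_perm": config.n_perm,
            "n_null_iter": config.n_null_iter,
        },
        "stages": {},
    }

    def _stage(name):
        d = out / name
        d.mkdir(exist_ok=True)
        manifest["stages"][name] = {"dir": str(d), "started": time.time() - t0}
        logger.info("stage %s started", name)
        return d

    # -- inputs ---------------------------------------------------------
    if config.synthetic is not None:
        d = _stage("simulate")
        spec = config.synthetic
        if spec.seed != seeds["simulate"]:
            # re-key the generator to the pipeline seed for whole-run determinism
            spec = SyntheticSpec(**{**spec.__dict__, "seed": seeds["simulate"]})
        dataset = generate_experiment(spec)
        emit_dataset(dataset, d)
        counts, design = dataset.counts, dataset.design
        manifest["stages"]["simulate"]["n_samples"] = counts.n_samples
        manifest["stages"]["simulate"]["n_cultures"] = dataset.n_cultures
    else:
        counts = read_community_table(config.otu_table)
        design = read_metadata(config.metadata)
        missing = [s for s in counts.sample_ids
                   if s not in set(design.table["sample_id"])]
        if missing:
            raise CommunityMatrixError(
                f"validation: {len(missing)} samples lack metadata, e.g. {missing[:3]}"
            )
        manifest["inputs"] = {
            "otu_table": {"path": config.otu_table, "sha256": _checksum(Path(config.otu_table))},
            "metadata": {"path": config.metadata, "sha256": _checksum(Path(config.metadata))},
        }

    final_day = int(design.table["day"].max())
    parent_day = final_day if config.parent_day is None else config.parent_day

    # -- rarefy ---------------------------------------------------------
    d = _stage("rarefy")
    rarefied = rarefy(counts, config.rarefaction_depth, seed=seeds["rarefy"])
    write_community_table(rarefied, d / "rarefied_otu_table.tsv")
    manifest["stages"]["rarefy"]["n_samples_kept"] = rarefied.n_samples

    # -- alpha diversity (rarefied) --------------------------------------
    d = _stage("diversity")
    adiv = alpha_diversity(rarefied)
    adiv.to_csv(d / "alpha_diversity.tsv", sep="\t")
    day_groups = _group_tables(rarefied, design, final_day)
    adiv_groups = {tag: adiv.loc[[s for s in g.sample_ids if s in adiv.index]]
                   for tag, g in day_groups.items()}
    adiv_tests = compare_alpha(adiv_groups, alpha=config.alpha)
    adiv_tests.to_csv(d / "alpha_group_tests.tsv", sep="\t")

    # -- cohesion / stability (non-rarefied unless overridden) -----------
    d = _stage("cohesion")
    coh_input = rarefied if config.cohesion_on_rarefied else counts
    coh = cohesion_pipeline(
        coh_input,
        prevalence_threshold=config.prevalence_threshold,
        n_iter=config.n_null_iter,
        seed=seeds["cohesion"],
    )
    coh.connectedness.to_csv(d / "connectedness.tsv", sep="\t")
    per_sample = coh.cohesion.copy()
    per_sample["stability"] = coh.stability
    per_sample.to_csv(d / "cohesion.tsv", sep="\t")
    with open(d / "run_manifest.json", "w") as fh:
        json.dump({"seed": coh.seed, "n_iter": coh.n_null_iterations,
                   "prevalence_threshold": coh.prevalence_threshold,
                   "on_rarefied": config.cohesion_on_rarefied}, fh, indent=2)
    sample_to_tag = {}
    for tag, g in _group_tables(coh_input, design, final_day).items():
        for s in g.sample_ids:
            sample_to_tag[s] = tag
    stab_groups: dict[str, list] = {}
    for s, v in coh.stability.items():
        if s in sample_to_tag:
            stab_groups.setdefault(sample_to_tag[s], []).append(v)
    stab_tests = compare_stability(stab_groups, alpha=config.alpha)
    stab_tests.to_csv(d / "stability_tests.tsv", sep="\t", index=False)

    # -- environmental screen -------------------------------------------
    d = _stage("screen")
    rel_rar = to_relative(rarefied)
    groups = _group_tables(rel_rar, design, final_day)
    screens: dict[str, list] = {}
    for parent, env in (("R", "Rx"), ("S", "Sx")):
        if parent not in groups or env not in groups:
            raise CommunityMatrixError(
                f"screen: missing treatment {parent!r} or {env!r} at day {final_day}"
            )
        da = permutation_da_test(
            groups[parent], groups[env],
            n_perm=config.n_perm, seed=seeds[f"screen_{parent}"], alpha=config.alpha,
        )
        da.table.to_csv(d / f"da_{parent}_vs_{env}.tsv", sep="\t")
        screens[parent] = environmental_screen(
            groups[parent], groups[env], da, alpha=config.alpha
        )
        pd.Series(screens[parent], name="taxon_id").to_csv(
            d / f"screened_{parent}.tsv", sep="\t", index=False
        )
        manifest["stages"]["screen"][f"n_retained_{parent}"] = len(screens[parent])

    # -- mixing model ----------------------------------------------------
    d = _stage("mixing")
    parent_groups = _group_tables(rel_rar, design, parent_day)
    rep_of = dict(zip(design.table["sample_id"], design.table["replicate"]))

    def _by_replicate(cm: CommunityMatrix) -> pd.DataFrame:
        df = cm.data.copy()
        df.index = [rep_of[s] for s in df.index]
        return df

    coalesced_tags = [t for t in groups if t.startswith(("OC_", "RC_"))]
    expectations = {}
    for tag in sorted(coalesced_tags):
        mode, ratio_s = tag.split("_")
        r, s = (int(x) for x in ratio_s.split(":"))
        expectations[tag] = build_expectation(
            _by_replicate(parent_groups["R"]),
            _by_replicate(parent_groups["S"]),
            _by_replicate(groups[tag]),
            (r, s),
            treatment=tag,
        )
    expectation_table(expectations).to_csv(d / "mixing_similarities.tsv", sep="\t", index=False)
    pred = predictability(expectations, alpha=config.alpha)
    convergence = {tag: parent_convergence(me, alpha=config.alpha).to_dict(orient="index")
                   for tag, me in expectations.items()}
    with open(d / "predictability.json", "w") as fh:
        json.dump({"predictability": pred, "parent_convergence": convergence}, fh, indent=2)

    # -- biotic response -------------------------------------------------
    d = _stage("respond")
    response_sets: dict[str, dict[str, list]] = {}
    respond_seeds = _child_seeds(seeds["respond"], len(coalesced_tags))
    for tag, rseed in zip(sorted(coalesced_tags), respond_seeds):
        mode, ratio_s = tag.split("_")
        r, s = (int(x) for x in ratio_s.split(":"))
        # reference: the ratio-weighted expected parent mixture (paired replicates)
        exp_df = expectations[tag].expected
        ref = CommunityMatrix(
            exp_df.div(exp_df.sum(axis=1), axis=0).set_axis(
                [f"EXP_{tag}_{k}" for k in exp_df.index]
            ),
            "relative",
        )
        screened = sorted(set(screens["R"]) | set(screens["S"]))
        da = biotic_response(
            groups[tag], ref, screened,
            n_perm=config.n_perm, seed=rseed, alpha=config.alpha,
            prevalence_threshold=config.prevalence_threshold,
        )
        da.table.to_csv(d / f"response_{tag}.tsv", sep="\t")
        response_sets[tag] = {"increased": da.increased, "decreased": da.decreased}
    with open(d / "response_sets.json", "w") as fh:
        json.dump(response_sets, fh, indent=2)

    # -- aggregate response ----------------------------------------------
    d = _stage("aggregate")
    agg_out = {}
    for direction in ("increased", "decreased"):
        union = sorted({t for sets in response_sets.values() for t in sets[direction]})
        totals, test = aggregate_response(
            {tag: groups[tag] for tag in coalesced_tags}, union
        )
        totals.to_csv(d / f"totals_{direction}.tsv", sep="\t", index=False)
        agg_out[direction] = {"n_taxa": len(union), "test": test}
    with open(d / "aggregate_tests.json", "w") as fh:
        json.dump(agg_out, fh, indent=2)

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline finished in %.1f s", manifest["runtime_seconds"])
    return manifest
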