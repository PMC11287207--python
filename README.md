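# coalmix

Analysis toolkit for **microbial community coalescence** experiments — what
happens when two whole communities (and their environments) from previously
separate habitats are mixed.  The motivating design is an estuarine-style
microcosm study: a freshwater river community (R) and a brackish sea
community (S) are combined at volumetric river:sea ratios (1:1, 1:2, 2:1),
either once (OC) or repeatedly (RC, 20% volume replaced with fresh parent
mixture every 4 days), over a 16-day incubation with five replicates,
alongside environmental-coalescence controls (R<sub>x</sub>, S<sub>x</sub>:
each unmixed parent in the blended 1:1 medium).

The package implements the full analysis chain for such OTU-table data and
ships a synthetic experiment generator with planted ground truth, so every
stage is testable end to end without any downloads.

## What it computes

**Cohesion and community stability.** For taxa passing a prevalence filter
(> 10% of samples), pairwise product–moment correlations *r<sub>ij</sub>*
are computed across samples on relative abundances of the non-rarefied
table, and corrected by a taxon-shuffle null model: each taxon's abundance
vector is permuted across samples (default 200 iterations) and the mean
permuted correlation is subtracted.  A taxon's **connectedness** is the
mean of its strictly positive (resp. strictly negative) corrected
correlations; per-sample **cohesion** is the abundance-weighted sum

&nbsp;&nbsp;C<sup>±</sup>(s) = Σ<sub>j</sub> a<sub>sj</sub> · conn<sup>±</sup>(j),

and the **stability ratio** |C<sup>−</sup>/C<sup>+</sup>| indexes the
balance of competition over facilitation/synchrony: below 1, positive
feedback loops dominate (lower stability); above 1, negative feedback
dampens perturbations.

**Conservative mixing model.** The expected coalesced composition at ratio
r:s is the convex combination E = (r·R + s·S)/(r+s) of the replicate-paired
parent compositions.  Predictability is the Bray–Curtis similarity
1 − Σ|x−y|/Σ(x+y) between observed and expected communities (one-sample
t-test on the deviations; one-way ANOVA + Tukey HSD across treatments), and
paired observed-vs-expected similarities to each parent classify outcomes
as convergence toward or divergence from R or S.

**Environmental/biotic decomposition.** A two-sided label-permutation test
(999 permutations, difference of group means on relative abundances,
Benjamini–Hochberg FDR) compares each parent with its environmental
control; taxa present in both groups and not significantly decreased pass
the **environmental screen**.  Abundance shifts of screened taxa in the
coalesced communities relative to the expected parent mixture are then
attributed to the **biotic** component of coalescence, and total relative
abundances of responding taxa are compared across treatments with
Kruskal–Wallis tests.

**Supporting operations.** TSV OTU-table and metadata I/O, exact
rarefaction without replacement, prevalence filtering, shared/unique taxon
sets, alpha diversity (richness, Shannon ln-based, inverse Simpson) with
Tukey-letter group comparisons, and 2-of-3 majority-rule consensus
taxonomy across three reference databases.

## Worked example

```python
from coalmix import PipelineConfig, SyntheticSpec, run_pipeline

manifest = run_pipeline(
    PipelineConfig(synthetic=SyntheticSpec(seed=7), seed=7,
                   out_dir="scratch/example_pipeline")
)
```

Running `python examples/full_pipeline.py` (which does the above and reads
back the outputs) prints:

```
stages: simulate, rarefy, diversity, cohesion, screen, mixing, respond, aggregate
runtime: 3.9 s
most predictable treatment: RC_1:2 (mean obs-exp similarity 0.818)
taxa decreased after coalescence: 30 (Kruskal-Wallis across treatments p=6.64e-05)
```

The most predictable treatment is the repeatedly coalesced, sea-dominated
mixture: repeated re-addition of the parents pulls the community back
toward the mixing-model expectation, and the planted sea-fitness advantage
means sea-dominated expectations are closest to where the community ends up
anyway.  The 30 decreased taxa are river specialists suppressed beyond what
conservative mixing predicts — the biotic footprint of coalescence.  The
other scripts in `examples/` walk through each capability (simulation,
cohesion/stability, mixing-model predictability, environmental screening,
diversity and consensus taxonomy) in the same style.

A thin CLI mirrors the pipeline for shell use:

```bash
coalmix simulate --seed 42 --out-dir data/
coalmix run-all --otu-table data/otu_table.tsv --metadata data/metadata.tsv \
        --seed 42 --out-dir results/
```

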