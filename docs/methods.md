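# Methods

This note documents the models, statistics and numerical choices behind
`coalmix`, and what the synthetic-data studies do and do not demonstrate.

## Cohesion and the stability ratio

Correlations are product–moment, computed across samples on relative
abundances of the **non-rarefied** counts table (rarefaction discards
information the correlation estimates can use; the package hard-wires this
choice in the pipeline, with an override flag).  Taxa must pass a
prevalence filter (strictly more than 10% of samples by default) before
entering the correlation step; pairs involving a zero-variance taxon are
set to 0 and excluded from connectedness means.

The null model is a *taxon shuffle*: for the ordered pair (i, j), taxon
j's abundance vector is permuted across samples, the correlation with the
unpermuted taxon i recomputed, and the mean over `n_iter` permutations
(default 200) taken as the null expectation; the matrix is symmetrised by
averaging the (i, j) and (j, i) estimates.  The corrected correlation is
observed minus null.  Permuting a single taxon rather than whole samples
preserves each taxon's marginal abundance distribution while destroying
cross-sample alignment, which is exactly the component the correction
should remove.  With 4 samples the null is enumerable over all 24
permutations, which the tests use as an exact oracle for the Monte-Carlo
estimator.

Connectedness splits the corrected correlations of each taxon into the
mean over strictly positive and strictly negative entries (0 when a side
is empty).  Cohesion is the abundance-weighted sum of connectedness per
sample, and stability is |negative : positive| cohesion.  When positive
cohesion is zero the ratio is undefined and propagates as NaN (logged),
never as infinity or an exception; group comparisons drop NaN values.  By
default connectedness is estimated over all samples jointly; a
`samples_for_connectedness` argument restricts the estimation set when a
per-treatment network is wanted instead — with only five replicates per
treatment the joint estimate is far less noisy, which is why it is the
default.

A caveat worth knowing: on relative abundances the compositional closure
(rows sum to one) induces a small negative dependence between taxa of
order −1/T for T exchangeable taxa.  Real communities are strongly uneven,
which concentrates that artefact on the dominant taxa and keeps the mean
corrected correlation within ±0.02 in the calibration study; perfectly
even synthetic communities would sit right at the artefact's worst case.

## Conservative mixing model

The expected coalesced composition at river:sea ratio r:s is
E = (r·R + s·S)/(r+s) on the union taxon set.  Expected communities are
built per replicate, pairing parent replicate "A" with coalesced replicate
"A" — mirroring the experimental protocol in which each replicate received
medium or parent community from its letter-matched bottle.  The parent
snapshot defaults to the final sampling day (day 16); the initial inocula
(day 0) can be selected instead via the pipeline's `parent_day`.

"Similarity" is 1 − Bray–Curtis dissimilarity throughout, computed on
relative abundances of the rarefied table in the pipeline.  The deviation
test is a one-sample t-test of (1 − similarity) against zero: when every
similarity is exactly 1 the statistic is defined as 0 with p = 1 rather
than the 0/0 a t-test would produce.  An alternative reading of "tested
with t-tests" — pairing observed and expected per replicate — gives the
same deviations here because the expectation is deterministic given the
parents; the one-sample construction is the one implemented.  Convergence
classification uses a paired t-test of similarity-to-parent, observed vs
expected, per parent; significant positive mean difference is convergence,
negative is divergence.

## Permutation differential abundance

The per-taxon test statistic is the difference of group means of relative
abundances; significance comes from random reassignment of sample labels
(default 999 permutations) with the +1-corrected p-value
p = (1 + #exceedances)/(1 + n_perm), so the smallest attainable p is
1/(n_perm + 1).  Exceedances are counted with a **strict** inequality
(|stat*| > |stat| + 1e-12): at five-versus-five samples random label
permutations recreate the observed split about once per 126 draws, and
counting those ties as exceedances would bound p away from the minimum
regardless of effect size, destroying FDR-corrected power at the
experiment's replication level.  A taxon whose observed statistic is
exactly zero is assigned p = 1 (a constant taxon must never look
significant).  The type-I study shows the resulting test is, if anything,
conservative after Benjamini–Hochberg correction at these sample sizes.

This permutation test stands in for more elaborate differential-abundance
machinery (reference-taxon ratios, winsorisation, omnibus statistics):
the downstream logic consumes only a per-taxon direction and an
FDR-adjusted significance call, and the test is pluggable behind that
interface.  BH adjustment itself is delegated to
`statsmodels.stats.multitest` and cross-checked against the step-up
definition in the tests.

The environmental screen retains taxa that are present (nonzero in at
least one replicate) in both the parent and its environmental control and
show no significant decrease; significant *increases* are retained, per
the screen's purpose of removing only environmentally suppressed taxa.
The biotic-response test runs on screened taxa with > 10% prevalence over
the combined sample set, against the **ratio-weighted expected parent
mixture** as reference (consistent with the mixing model; testing against
each parent separately is available by passing that parent as the
reference).  FDR control is applied across the taxa actually tested.

## Alpha diversity and group tests

Richness counts nonzero taxa; Shannon uses the natural logarithm; inverse
Simpson is 1/Σp².  Group differences use one-way ANOVA with Tukey's HSD
and a compact letter display.  The classical multiple-range post hoc often
seen in this literature (Duncan's) is weakly protected and rarely
implemented outside legacy stacks; Tukey HSD is the standard, slightly
more conservative replacement.

## Synthetic experiment generator

The generator emulates the microcosm design: river and sea taxon pools of
120 taxa sharing 60, base compositions drawn from a Dirichlet with
concentration 0.3 (strongly uneven, as in real communities), and replicate
compositions resampled around each base with Dirichlet precision 600 —
replicates seeded from one homogenised inoculum agree to roughly a 40%
coefficient of variation for a 1%-abundance taxon.  Counts are multinomial
at depth 5000 per sample, the order of the study design's rarefaction
depth (4752).

Planted structure, all on the abundant taxa so it is detectable in
relative-abundance data:

- a **positive block** of 10 shared taxa riding a common lognormal factor
  (σ = 0.5) per observation — facilitation or environmental synchrony;
- five **anti-phase pairs** implemented as a share-conserving see-saw: the
  pair's total share is redistributed by a Beta(b, b) draw with
  b = 1/(1 + loading).  The see-saw deliberately conserves the pair's
  total so the coupling does not leak positive correlation into the rest
  of the composition through the closure denominator — a multiplicative
  h / 1/h scheme was found to do exactly that;
- ten **environment-sensitive** specialists per habitat whose latent
  abundance is multiplied by 0.05 in the blended medium (Rx/Sx);
- per-taxon **fitness in mixed medium**, blended by the foreign-medium
  volume fraction w: river specialists grow by 0.2^w per 4-day step
  (salinity beyond their tolerance), sea specialists by 1.8^(1−w)
  (exploiting the nitrogen-rich river medium), shared taxa are
  generalists at 1.  These defaults encode the asymmetric,
  sea-advantaged coalescence the design anticipates; they produce the
  directional pattern (1:2 most predictable, 2:1 least; coalesced
  communities closer to the sea parent) as an emergent outcome of the
  dynamics, not as anything written into the analysis code.

Coalesced trajectories start from the replicate-paired convex mixture and
apply one growth step plus one exchange per 4-day interval: OC exchanges
cell-free medium (pure dilution — a no-op on proportions, since
sterile-filtered media carry no microeukaryotes), RC replaces 20% of the
volume with the fresh parent mixture, a contraction toward the expectation
that makes repeated coalescence more predictable.  The emitted day-16
layout is 10 community treatments × 5 replicates = 50 samples; the
experiment's 60 incubated cultures additionally count the per-replicate
sterile media bottles (R_m, S_m), which contain no community and therefore
never appear in the OTU table.

What the generator does **not** model: bacterial dynamics and trophic
interactions (grazing, parasitism), nutrient chemistry, mechanistic
growth (no Lotka–Volterra integration — interactions enter only through
the planted latent factors), sequencing error or chimeras, and
compositional bias between taxa.  Passing the recovery studies therefore
shows the chain detects the planted effects under multinomial sampling
noise and replicate variation; it does not certify performance under,
e.g., strong trophic feedbacks or library-preparation bias.

## Determinism and problem sizes

All randomness flows from a single seed via
`numpy.random.SeedSequence(seed)`; the pipeline derives one child seed per
stage (folded below 2³¹) and records them in the run manifest together
with parameter values and input checksums, so any output file can be
regenerated bit-for-bit.

The validation studies use desk-scale problem sizes chosen to estimate
each property with comfortable margins: 20 seeds × (40 samples × 50 taxa)
for null calibration; 100 seeds for block recovery; a 6-level planted-
competition sweep at 20 seeds × 250 samples per level (the sweep is
paired — the random draws are nested so higher levels extend the same
realisation); 100 null simulations for type-I error; 50 simulated
experiments for screen recovery; and 100 for the directional
predictability pattern.

## Known limitations

- The cohesion correction reduces, but cannot remove, compositional
  dependence; connectedness contrasts between taxa are more trustworthy
  than absolute values.
- At five replicates the permutation test has a discrete null (126
  distinct splits); p-values are granular and FDR-corrected discovery
  needs near-complete separation.
- The stability ratio is noisy for single communities; comparisons should
  pool replicates or samples, as the examples do.
- Consensus taxonomy is exact-match by rank and does not reconcile
  synonymous names across reference databases.
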