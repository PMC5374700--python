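# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `netmdc`.

## Networks

**Correlation network (CN).** The adjacency is *a_ij* = |*r_ij*| with
*r_ij* the Pearson correlation of the two genes' expression profiles.
The unsigned form is the default everywhere, including inside MDC
averages: connectivity is meant to measure the magnitude of
co-regulation, and an unsigned network lets anticorrelated genes
co-cluster. The signed correlations are always retained alongside
(`signed_source`) for diagnostics, and `pearson_adjacency(signed=True)`
exposes an experimental signed mode. The diagonal is defined as 0 and
excluded from every connectivity average. Inference requires ≥ 3
samples and rejects constant genes by name.

**Scale-free network (SFN).** Hard thresholding: an edge is kept iff
*a_ij* ≥ τ, with τ chosen from a candidate grid (default 0.10–0.95 in
steps of 0.05) as the smallest value whose degree distribution fits a
power law. The fit regresses log10 p(k) on log10 k over 10
equal-occupancy degree bins and requires a negative slope; a threshold
passes at R² ≥ 0.85 (a conventional choice — both grid
and criterion are configurable). Degenerate degree distributions
(e.g. a complete graph) are flagged unusable. The thresholded adjacency
is then transformed to topological overlap,

    TOM_ij = (l_ij + â_ij) / (min(k_i, k_j) + 1 − â_ij),
    l_ij = Σ_u â_iu â_uj,  k_i = Σ_u â_iu,

which credits shared neighbors. The split-half validation below shows
why CN is the recommended default.

**Partial-correlation network.** For aggregate compound networks the
pooled samples mix compounds whose mean expression differs, which by
itself induces spurious correlation. Expression is therefore
residualized per gene on the compound label (per-level mean removal —
algebraically identical to partialling out compound indicator
covariates) before correlating. Full inverse-covariance partial
correlation is deliberately out of scope: with thousands of genes and
tens of samples the precision matrix is not estimable. Each covariate
level needs ≥ 2 samples and the residual degrees of freedom must be
≥ 3.

## Module detection (dynamic hybrid tree cut)

Modules are detected on *d_ij* = 1 − *a_ij* by Ward linkage followed by
a dynamic hybrid cut, reimplemented here (no maintained Python port was
available). The dendrogram is walked top-down; a merge is split into
its two branches when

1. both branches contain ≥ `min_cluster_size` leaves (default 10),
2. the normalized **gap** between the merge height and the 0.9 quantile
   of each branch's internal merge heights exceeds a deepSplit-dependent
   minimum, and
3. each branch's **core scatter** (mean normalized internal merge
   height) is below a deepSplit-dependent ceiling.

Using a quantile of the branch's merge heights rather than its single
top merge lets the walk descend through stacked high-level joins — a
branch that itself holds several well-separated clusters merges almost
as high as its parent. A small twig (< min size) hanging off a clear
gap is trimmed to "unassigned" while descent continues. deepSplit ∈
{0..4} maps to core-scatter ceilings (0.64, 0.73, 0.82, 0.91, 0.95)
and minimum gap (1 − ceiling) · 3/4, following the reference tool's
interpolated parameters; the default 4 yields many homogeneous
modules. Heights are normalized to [0, 1] between the 5th percentile
and the maximum merge height; a flat dendrogram (zero range) returns a
single degenerate cluster, flagged by construction.

Afterwards, unassigned objects join the cluster with the smallest mean
dissimilarity, but only if they are closer to it than to the remaining
objects (a PAM-like stage); otherwise they keep label 0. Labels are
canonicalized 1..K by decreasing size, with WGCNA-style color names as
cosmetic aliases. The procedure is deterministic; its contract is
recovery of well-separated planted structure (verified over 20 seeds),
not numerical agreement with the R implementation.

The same cut, with minimum size 3, groups compounds on the 1 − aRI
distance between their network module partitions.

## MDC and significance

`MDC(X, Y) = |EN_X| / |EN_Y|` with |EN| the mean adjacency over
unordered within-module pairs. `compute_gdc` applies the same ratio to
the whole gene universe. Identity holds exactly (a network against
itself gives 1 for every module) and MDC(X,Y)·MDC(Y,X) = 1.

**Bootstrap.** The reference samples (controls for the
control-centered analysis; the pooled perturbation samples for the
aggregate-centered one) are resampled with replacement at the perturbed
network's sample size; each resample's network yields a per-module log
MDC against the full-reference network. The two-sided p-value uses the
add-one estimator p = (1 + #{|null| ≥ |observed|}) / (1 + B), B = 1000
by default (≥ 100 enforced), with BH q-values across modules. Genes
constant within a resample contribute zero adjacency. The alternative
permutation scheme over random gene sets is provided only as a
comparison utility (`permutation_mdc_pvalues`); it is far less
stringent and is not part of the pipeline.

*Limitation:* the bootstrap captures sampling variability at the
perturbed sample size but not the reference network's own estimation
noise. With a reference much larger than the target (the intended
regime) the effect is small; with comparable sizes the p-values are
somewhat anticonservative. The calibration test accordingly verifies
exchangeability with the resampling null itself.

## Specificity and frequency classes

Sp(m)_g = Σ_{k≠g} |log MDC_m(g) − log MDC_m(g_k)|; for high-frequency
aggregate modules the reported score is Sp/Ntot with Ntot the total
number of groups. Selection takes, per compound group, the (module,
group) pairs strictly exceeding the 95th percentile (linear
interpolation) of the *globally pooled* score distribution — the
pooling scope is configurable but global is the default reading of an
"overall distribution". Sp is invariant to adding a constant to a
module's log MDCs and scales linearly with them.

A module of one aggregate network is "observed" in another if some
module there overlaps it with one-sided Fisher p < 0.01; modules
observed in strictly more than half of the aggregate networks are
high-frequency, the rest low-frequency and carried forward only when
their own bootstrap p < 0.01.

## Enrichment and annotation similarity

Module annotation uses the one-sided hypergeometric upper tail
(identical to the one-sided Fisher exact test) against each gene set,
restricted to the filtered gene universe, BH-corrected across sets,
reporting FDR ≤ 0.25. Compound-group coherence is the median pairwise
Fisher p of annotation (protein / side-effect) overlap among member
compounds; its significance compares against 1000 random equally sized
compound groups, p = (1 + #{score ≤ observed}) / (1 + n_perm), with a
flag when no permutation beats the observed score. Compounds without
annotations are excluded and reported (NA semantics).

## Preprocessing

The variation filter ranks genes by the unscaled median absolute
deviation (the 1.4826 consistency constant cancels in ranking) over
*all* samples — control and treated combined, so every network shares
one gene universe — and keeps the top k = 7000 by default. Ties at the
cutoff break by input order; the filter is scale-equivariant and
idempotent.

## Validation harness

**Split-half.** Samples are repeatedly split into disjoint equal
halves; modules come from the first half's network and the MDC of the
second-half network against the first is recorded per module. On a
homogeneous dataset the distribution should center at 1; the CN method
achieves this with markedly lower spread than SFN, whose per-half
threshold re-selection amplifies sampling noise (thresholded modules
can even lose all edges in the other half, in which case their MDC is
undefined and skipped). A correlation-scale factor in the generator
reproduces the cross-dataset artifact in which a batch-level shift of
the correlation-magnitude distribution drives MDC systematically away
from 1 even though module composition replicates.

**Power.** Power to detect a true correlation ρ at level α is computed
analytically (Fisher z with the small-sample mean correction
E[z] ≈ atanh ρ + ρ/(2(n−1)), rejection region from the exact t-test
critical value mapped to the z scale) or by Monte-Carlo simulation of
the t-test on bivariate-normal draws. The test's sidedness was pinned
by simulation: the one-sided convention yields power 0.50 at n = 11 and
0.95 at n = 38 for ρ = 0.5, α = 0.05 — the regime of 11–38 replicates
per compound network — whereas the two-sided convention (0.36, 0.91)
does not; one-sided is therefore the default.

## Synthetic cohorts

The generator emulates a compound-screen compendium at desk scale:
genes are drawn from a Gaussian block-equicorrelation model (within
module m, condition k, every pair has correlation ρ_{m,k};
ρ ∈ [0, 1) guarantees positive definiteness), with per-gene baseline
intensities N(8, 1) on the log2 scale, optional per-compound mean
shifts on chosen modules (to exercise the partial-correlation control)
and an optional correlation-scale factor (to exercise the batch
artifact). Default conditions follow the study design the package
targets: 18 replicate samples per compound (the typical replicate
count, range 11–38), ≥ 10 replicates required for a compound network,
compound groups of ≥ 3. Annotations plant a shared item core per
compound group with a configurable sharing fraction. Every planted
parameter is serialized in a truth record.

What the generator does *not* emulate: probe-level microarray noise,
heavy-tailed expression, platform effects beyond the correlation-scale
factor, or realistic pathway topology — passing recovery tests shows
the algorithms recover the planted correlation structure, not that
real-data modules are biologically correct.

Desk-scale problem sizes used by the test suite and the acceptance
script (chosen so the full pipeline properties remain testable on a
single CPU): split-half calibration uses 500 genes in ten 50-gene
modules (ρ 0.3–0.6) with 400 samples and 50 repetitions; planted-block
recovery uses three 50-gene blocks at ρ 0.8 with 100 samples over 20
seeds; the two-family grouping design uses four 35-gene blocks
(families strong, ρ 0.8, on disjoint block pairs; 4 compounds × 25
samples each) — with blocks shared between families, the "off" family's
leftover genes form a cluster coinciding with the other family's module
and confound the aRI at this scale. Power anchors use 100,000
simulation draws.

## Pipeline defaults

MAD k = 7000; min replicates 10; module min size 10, deepSplit 4;
group min size 3, deepSplit 4; bootstrap 1000; permutations 1000;
specificity percentile 5; enrichment FDR ≤ 0.25; high-frequency
threshold 50%. One global seed is expanded into per-stage seeds via
`SeedSequence([seed, crc32(stage)])`, so stages are reproducible
independently; a resolved copy of the configuration is written next to
every run's outputs.
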