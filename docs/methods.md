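# Methods

## The analysis model

The unit of analysis is a **stratum**: one morphological niche (endo, epi,
rhizo, sediment or water) on one feature axis (taxonomic OTUs or functional
categories).  Within a stratum the community response to a pulse
perturbation is summarised by Bray–Curtis dissimilarity,
BC(x, y) = 1 − 2·Σᵢ min(xᵢ, yᵢ) / (Σᵢ xᵢ + Σᵢ yᵢ), computed on
compositionally transformed (relative-abundance) tables after rarefaction.
The distance-to-control construction treats BC as the response variable:

* `C_t` — mean pairwise BC **among control replicates** at timepoint *t*.
  This is the control level of the response: control replicates are never at
  distance zero from "the control community", so the baseline is their own
  dispersion.  A timepoint with fewer than two control replicates leaves
  `C_t` undefined and invalidates the contrast (flagged, not imputed).
* `D_t` — mean BC over all treatment-replicate × control-replicate pairs at
  timepoint *t*, pooled across experimental patches within the niche
  (per-patch stratification is available via the `experiment` argument).

Timepoints follow the pulse design: T0 (day 0, pre-stress), T1 (day 3,
directly after the pulse), T2 (day 12, after recovery).  Contrasts use
same-timepoint controls, so temporal drift common to all arms cancels.

The Orwin–Wardle indices are

    RS = 1 − 2·|C1 − D1| / (C1 + |C1 − D1|)
    RL = 2·|C1 − D1| / (|C1 − D1| + |C2 − D2|) − 1

Absolute values are used in both numerator terms; without them RS could
exceed 1 whenever D1 < C1, contradicting its definition as a [−1, 1] index.
RS is **not clamped** to [0, 1]: the formula admits negative values for
displacements larger than twice the baseline and we report them as computed.
Undefined cases — RS with C1 = D1 = 0, RL with both displacements zero (a
fully resistant community has no recovery to measure) — carry explicit
`*_defined` flags instead of sentinel values.

## Supporting statistics

**PERMANOVA.**  Sequential (Type I) sums of squares in the style of vegan's
`adonis2(..., by = "terms")`: the squared-distance matrix is Gower-centred
(G = −½·J·D²·J), each term's SS is the increase in tr(H·G) as its
dummy-coded columns join the design (rank-revealing SVD bases; a term adding
no rank is reported as confounded), and each pseudo-F uses the full-model
residual.  p-values come from free permutation of the rows/columns of G with
the observed statistic included: p = (1 + #{F* ≥ F}) / (1 + n_perm).  The
comparison uses a relative tolerance of 1e-8 so permutations exactly tied
with the observed statistic are counted despite recomputation-order float
jitter; without it the identity-equivalent permutations (a ~10 % mass on
small balanced designs) would be silently dropped and p would be
anti-conservative.  Implementation is checked against vegan's `adonis2` in
the test suite.

**ANOVA on distances.**  One-way ANOVA on per-sample distance values, with
all pairwise least-squares-mean contrasts using the pooled error variance
(df = N − k).  Multiplicity is handled by Holm's step-down procedure — a
distribution-free, uniformly conservative replacement for single-step
multivariate-t adjustment, whose quantile computation adds implementation
weight for a second-order effect.

**IndVal.g.**  For feature *i* and a combination *g* of group levels:
A (specificity, group-size corrected) = Σ_{k∈g} x̄ᵢₖ / Σ_{all k} x̄ᵢₖ using
per-group **mean** abundances, B (fidelity) = occupancy fraction in *g*,
stat = √(A·B).  All non-empty proper subsets up to `max_order` are scored
(the all-groups set is excluded — its A is trivially 1) and each feature
reports its best combination.  The permutation test permutes sample labels
and recomputes the maximum statistic, so the p-value accounts for combination
selection; `n_perm="exhaustive"` enumerates all distinct label assignments
for an exact p.  Zero-total features are dropped with a warning.

**PCoA.**  Classical scaling: eigendecomposition of the Gower-centred
matrix, coordinates scaled by √λ on positive axes.  Bray–Curtis is
non-Euclidean, so negative eigenvalues occur; they are reported unchanged
but contribute zero coordinates, and no Cailliez/Lingoes correction is
applied — transparency over adjustment.  Variance explained is relative to
the positive eigenvalue sum.

## Preprocessing

* **Lineage filter** — case-insensitive substring match over all ranks
  (classifiers label ranks inconsistently), defaults
  {Cyanobacteria, Chloroplast, Mitochondria, Mitochondrion}; unannotated
  features are retained; idempotent.
* **Rarefaction** — exact multivariate-hypergeometric subsampling to a
  common depth (default 2,821 reads).  Samples below depth are **dropped**
  (padding would invent reads) and logged; features left with zero total are
  pruned.  Per-sample RNG streams are derived by SHA-256 hashing of
  (seed, sample_id), so results are independent of sample order.
* **Functional tables** — a function × feature non-negative weight matrix
  maps taxa to functions by a linear product; integer-valued function tables
  are rarefied with the same algorithm (default depth = minimum sample sum,
  the least destructive common depth), non-integer ones go straight to the
  compositional transform.

## The synthetic study generator

The generator emulates the statistical structure the analysis assumes, with
every sample's noise-free latent composition retained; the ground-truth
stability table is **by definition** the stability module run on those
latents, so estimator checks are closed under the package's own machinery.

Per niche, a base composition is drawn from log-normal abundances
(σ = 1.5, a steep realistic rank-abundance curve) over a pool of features
(default 500) sharing a configurable core fraction (default 0.3) across
niches.  Condition means are formed multiplicatively on the simplex: a
responsive subset (default 10 % per niche × treatment, half shifted up and
half down to keep the mean composition comparable and exercise both
indicator directions) is multiplied by exp(±δ) at T1; at T2 the exponent is
scaled by (1 − ρ), ρ being the recovery fraction; all arms of a niche share
a per-timepoint log-scale drift (σ = 0.05).  Replicates are
Dirichlet(κ·mean) draws; counts are multinomial at log-normal depth
(mean 28,000, σ_log = 0.5, matching the heavy right tail of amplicon runs).

**Replicate heterogeneity κ = 300** puts mean within-condition Bray–Curtis
near 0.4 — typical of controlled mesocosm replicates — and keeps the
|C₂ − D₂| noise floor (folded-normal, ~0.01–0.03 with three replicates) low
enough that a fully reversed moderate pulse is detectable as positive
resilience.  Lower κ emulates field-survey-like heterogeneity, where
recovery detection at three replicates genuinely degrades.

What the generator does **not** emulate: phylogenetic correlation of
responses, taxon-specific depth biases (primer/copy-number effects),
overdispersed (Dirichlet-multinomial) counting noise beyond the latent
Dirichlet layer, batch effects between sequencing runs, or time courses
beyond the three design timepoints.  Passing recovery tests therefore shows
the estimator chain is consistent under multinomial sampling and replicate
heterogeneity — not that it is robust to those unmodelled features.

## Problem sizes and numerical choices

Simulation-based checks run at 500 features per niche, two or three niches,
three replicates and depth 20,000 — large enough that count noise sits well
below the index scale, small enough to iterate comfortably.  Effect sizes
for recovery studies are calibrated by a grid search on latent truth
(`calibrate_effect_size`), targeting latent RS levels (strong ≈ 0.4,
mild ≈ 0.8) rather than raw δ, since the RS ↔ δ map depends on κ and the
feature pool.  Permutation tests default to 999 permutations (199 in the
bundled pipeline config for speed); permutation p-values always include the
observed assignment and can never be 0.  Relative-abundance columns are
validated to 1e-9; distance symmetry to 1e-12.  Worst-case per-treatment
index values in small designs fluctuate (a single contrast averages 3–9
distance pairs), so simulation assertions pin means across cells with a
floor on the worst cell.

## Known limitations

* `C_t` as control dispersion is one reading of the distance-to-control
  construction; with it, RS compares the treatment's *excess* displacement
  to the baseline dispersion, so very heterogeneous controls compress the
  observable RS range.
* Free (unrestricted) permutation is used throughout; restricted schemes
  (within-experiment, within-run) are not implemented.
* The IndVal permutation test is per-feature; no multiple-testing correction
  is applied across features (report-level filtering is left to the caller).
* BIOM support is the 1.0 JSON schema only (dense and sparse); HDF5 BIOM is
  out of scope.
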