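# Methods

`cofosnet` implements a whole-brain co-activation analysis for regional
c-Fos cell counts, together with a fibre-photometry peri-event analysis.
This note records the models, the parameters that matter, the synthetic
data the pipeline is validated on, and the design choices made where the
analysis recipe is genuinely open.

## Co-activation networks

**Input.** A region × subject table of c-Fos⁺ cell counts (regions named
by atlas acronyms) plus subject metadata (phenotype AGG/NON, sex, virus
group). One network is built per subject group.

**Correlation.** `s_ij` is the Pearson correlation of counts between
regions *i* and *j* across the group's subjects (Spearman selectable).
Zero-variance regions are dropped with a warning by default (or kept with
`s = 0` via a switch).

**Soft thresholding.** The power adjacency `a_ij = |s_ij|^β` maps
correlations to edge weights in [0, 1] while suppressing weak,
potentially spurious correlations. Unsigned (absolute-value) adjacency is
the default because the TOM bound below requires `a ∈ [0, 1]`; a
signed-hybrid variant (`a_ij = s_ij^β` for positive `s`, else 0) is
selectable. `pick_soft_power` chooses the smallest candidate power whose
scale-free topology fit R² (log-log regression of binned degree
frequency on degree) exceeds 0.8, and falls back to the default with a
warning when no candidate qualifies — regional networks with tens of
nodes frequently have no convincing scale-free regime. The default power
is **β = 4**, calibrated on synthetic cohorts (latent within-module
correlation 0.5–0.6, 20–40 subjects): β ≤ 3 lets modules chain together
through background regions, β ≥ 5 shrinks within-module overlap into the
cut region (see below).

**Topological overlap.** Similarity for clustering is the topological
overlap measure

    ω_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_u a_iu a_uj  (u ∉ {i, j}),   k_i = Σ_{j≠i} a_ij,

which augments a direct connection with the regions' shared
neighbourhood and lies in [0, 1] with ω_ii = 1. The implementation is
vectorised; the test suite checks it against a literal triple-loop
evaluation to 1e-10.

**Module detection.** Average-linkage hierarchical clustering of the
dissimilarity `1 − TOM`, cut at height **0.96**, clusters smaller than
`min_module_size = 5` discarded to `unassigned`, followed by an
**affinity assignment stage**: an unassigned region joins the module it
has the highest mean TOM to, provided that affinity is at least half the
module's own mean internal TOM. This stage plays the role of the PAM
step in dynamic-hybrid tree cutting; a bare static cut proved fragile in
calibration because the absolute TOM scale varies with β and sampling
noise, so branch members drop off at any fixed height (module recovery
ARI ≥ 0.9 in only ~55–82 % of replicates for a bare 0.95 cut, vs 99 %
with the defaults above; 100 calibration replicates, four modules of
8–15 regions, correlation 0.6, 40 subjects). Modules are labelled by
decreasing size with conventional colour names; all clustering ties are
broken by lexicographic region order, so detection is a deterministic
function of the TOM.

## Module expression, connectivity and hubs

Per-subject **module expression** is the module-eigengene construction:
counts for the module's regions are standardized per region (zero mean,
unit variance across subjects) and the subject × region submatrix is
decomposed by SVD, `X = U S Vᵀ`. The leading left-singular vector gives
one score per subject; `σ₁²/Σσ_k²` is the proportion of variance
explained. Scores are sign-oriented to correlate positively with the
mean standardized profile, making results invariant to backend sign
conventions. A variant that decomposes the module's TOM submatrix is
available behind a flag for audit, but a region × region TOM cannot
yield per-subject scores, which is why the count-based construction is
the default.

Per-region statistics within a module: **kIM** (intramodular
connectivity, the sum of adjacency to the other members — hub ranking
sorts by kIM, ties lexicographic, and reports the mean within-module
edge weight kIM/(m−1)); **kME** (correlation of the region's counts with
the module scores, "module membership"); **MAR** (maximum adjacency
ratio, `Σa² / Σa`).

## Module preservation

A module defined in a reference network is scored in a test network by
five connectivity bases (correlations, over module regions, of the
reference vs test kIM, kME and MAR vectors; over all regions for kMEall;
and between the vectorized off-diagonal correlation submatrices for
cor.cor) and four density bases (proportion of variance explained in the
test data under reference membership; mean sign-aware test correlation
`mean sign(s_ref)·s_test`; mean within-module test adjacency; mean test
MAR). Each base `b` yields

    Z = (b_observed − mean(b_perm)) / sd(b_perm)

over permutations that shuffle module labels uniformly across the test
network's regions with module sizes preserved. One joint shuffle per
permutation drives all modules and all statistics — the statistically
coherent choice, since the statistics are then evaluated on a common
null draw. Degenerate permutation distributions (sd = 0) produce a
signed infinite Z and are flagged rather than silently numeric. An
optional median-of-Z summary is provided and explicitly marked as a
convention, not a literature-mandated composite.

**A scale limit worth knowing.** For a module of *m* regions, every
correlation-based connectivity Z is bounded: the permutation null of a
correlation over *m* points has sd ≈ 1/√(m−1), so even perfect
preservation (observed correlation 1) gives Z ≈ √(m−1) — about 3.7 for
m = 15, about 5.2 for m = 28. Strong preservation therefore shows up in
connectivity Z values of 2–4 for modules of this size, while density
statistics, whose permutation nulls are far tighter, reach Z of 10–20.
Comparisons between preservation runs should rely on the full metric
panel, not a single connectivity Z. Relatedly, connectivity preservation
is only informative for modules that *have* a connectivity profile: for
an exchangeable (equicorrelated) module every member has the same
expected kIM and the observed correlation is noise around zero. The
synthetic generator therefore supports a hub-to-periphery loading
gradient (`loading_spread`), and preservation validation uses graded
modules.

## Region-wise negative-binomial screen

For each region, counts are modelled as NB2 with a log link and a
two-level dummy-coded group contrast (0 = reference, 1 = comparison):
`log μ = β₀ + β₁·group`, `Var = μ + μ²/α`. Coefficients and the
dispersion α are joint maximum-likelihood estimates from iteratively
reweighted least squares (Fisher scoring with weights `μ/(1 + μ/α)`)
alternated with one-dimensional profile maximisation of α on the log
scale — the glm.nb fitting scheme. The reported z is β₁ over its
standard error from the Fisher information; p is two-sided normal;
q-values are Benjamini–Hochberg across regions (computed via
`statsmodels.multipletests`; the 0.05 significance threshold is the
caller's, not baked in). The model is intercept + group only (no
covariates); dispersion is estimated per region; zero inflation is not
modelled. Degenerate regions (all-zero counts, one group all zero,
non-convergence) return a flagged sentinel excluded from BH with a
warning, keeping the screen deterministic and total. Convergence uses a
relative log-likelihood tolerance of 1e-8 because the dispersion profile
is flat at its upper bound for quasi-Poisson data. The test suite checks
the fit against brute-force grid-plus-simplex likelihood maximisation
(coefficients to 1e-4) and against the independent statsmodels MLE.

The Wald z is asymptotic: at 12–15 subjects per group the null
false-positive rate at p < 0.05 runs near 0.08, a property of the test,
not of the implementation. Calibration checks therefore use 30 subjects
per group, where the measured rate is statistically compatible with the
nominal 5 %.

## Photometry

Preprocessing follows the acquisition protocol: 470 nm signal and 415 nm
control channels at 40 samples/s, a 2-minute event-free baseline;
`corrected = signal − control` (the literal channel difference; a
regression-based correction is available behind a flag);
`F0 = mean(corrected)` over the **final 60 s** of the baseline window
(F0 ≤ 0 is an explicit error — dF/F is undefined); `dF/F =
(corrected − F0)/F0`; and z-scoring of the dF/F trace, by default over
the whole session (a baseline-only variant is selectable; the protocol
wording does not disambiguate the two). Preprocessing is invariant to
affine rescaling of the raw fluorescence units.

Bout taxonomy: an investigation bout *precedes an attack* when an attack
starts within `gap_s` seconds (default 2 s, configurable and reported in
outputs — the transition window is not a measured quantity) after the
bout ends, otherwise it is *isolated*; an attack is *with prior
investigation* when an investigation ends within the same gap before its
start; sessions are labelled attack/no-attack days by the presence of any
attack. Classification is a pure function of the event table and the gap,
property-tested against a brute-force interval scan.

Peri-event extraction aligns the processed trace to bout onsets over a
(pre, post) window (default 4 s + 4 s; 2 s + 2 s used for odour-style
events); trials whose window leaves the recording are excluded and
counted, and zero usable trials yield an empty set, not an error.
Pre/post quantification uses per-trial window means, a paired Wilcoxon
test within a class (single-trial classes are descriptive only), and a
rank-sum test on post-minus-pre differences between classes. No ANOVA
replication is attempted.

## Synthetic data

The generator exists so every stage can be validated against planted
ground truth; real data never enters the pipeline's tests.

**Counts** come from a Gaussian copula: a latent MVN with a one-factor
block per module (equicorrelation ρ within, zero between; optional
loading gradient and hub multiplier) is pushed through the normal CDF
and mapped to NB quantiles with mean `nb_mean` and size `nb_dispersion`
(variance = μ + μ²/dispersion) — the simplest mechanism that produces
correlated overdispersed counts matching the NB model the screen
assumes, so the network and regression stages are jointly testable.
Group effects multiply μ for member regions. Background regions are
independent NB noise, giving module detection a null to reject. Defaults
emulate a typical aggression-mapping cohort: four groups
(AGG/NON × male/female) of 12
subjects, a dominant 28-region module elevated 1.5× in male aggressors,
two smaller modules, `nb_mean = 500`, `nb_dispersion = 8`. Reference
per-region count distributions are not available for such cohorts, so
the NB magnitudes are chosen for test power at realistic scales
(hundreds of cells, moderate overdispersion), not fitted to data.

**Photometry** sessions are two channels on a shared exponentially
bleaching baseline (single-exponential bleach, time-constant 600 s);
the signal channel carries a constant offset (GCaMP baseline brightness
above autofluorescence — the offset is what makes the control-subtracted
F0 positive) and difference-of-exponential transients (rise 0.2 s, decay
1.5 s, GCaMP6s-like) locked to event onsets, with amplitude expressed in
dF/F units relative to the offset. Gaussian noise is independent per
channel. The pipeline must be robust to, not dependent on, these shapes.

What the generator does **not** emulate: atlas registration error,
spatially correlated counting noise, heavy-tailed or zero-inflated
counts, sex- or litter-structured covariance, motion artifacts,
wavelength-dependent bleaching, or behavioural annotation jitter.
Passing tests therefore demonstrate algorithmic correctness and
statistical calibration under the stated model, not robustness to every
failure mode of real acquisitions.

## Problem sizes and determinism

Validation uses deliberately desk-sized problems: networks of 40–100
regions, cohorts of 12–30 subjects per group, 100–200 label
permutations, 20–100 simulation replicates per claim, and oracle
comparisons on ≤ 12-region instances where brute force is exact. All
randomness flows from explicit seeds through `numpy` Generators; the
pipeline stamps outputs with a config hash and seed, writes floats with
a fixed format, and reruns are byte-identical. `scripts/acceptance.py`
recomputes the headline quantities from scratch for any seed.

## Known limitations

- The correlation-Z ceiling above: single connectivity Z values are not
  comparable across module sizes.
- The static-plus-affinity cut is a deliberate simplification of full
  dynamic tree cutting; deeply nested or strongly unequal-density
  modules may still merge or shed members.
- The NB screen's small-sample anticonservatism is inherited from the
  Wald test; at n ≲ 15 per group, q-values should be read accordingly.
- Module colour names are size ranks, not identities: the same planted
  module can receive different colours in different runs; cross-network
  module identity is by region membership transfer, never by colour.
- Photometry bout classes depend on the configurable transition gap;
  2 s is a convention and all outputs record it.
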