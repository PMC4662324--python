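# Methods

This note documents the statistical models behind `phylodiet`, the
conventions adopted where several are defensible, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Diet indices from heterogeneous entries

An *entry* is one diet record for one species in one season/locality from
one study. Food items are binned into eight non-overlapping categories
(Leaves, Roots, Seeds, Fruits, Plants, Algae, Animal, Other; "Plants" is
plant material whose part was not identified, "Other" is anything else,
usually unidentifiable matter). Normalization is method-specific:

* *gut_percentage / feeding_time / fecal* report percentages already; they
  pass through when they sum to 100 ± 2 and are renormalized (with a
  warning) otherwise.
* *frequency_occurrence* counts are rescaled by their total.
* *qualitative* accounts score each consumed item on a 1 (rare) to 4
  (primary) scale from its descriptive adjective and normalize the scores.
  The default adjective table is
  `{primary(-ily)/chiefly/mainly: 4, important/major/frequent: 3,
  common/regular/also: 2, rare(-ly)/trace/occasionally: 1}`; items without
  a resolvable adjective score the scale midpoint (2.5), so an account
  with no usable adjectives weights its items equally. The table is an
  explicit argument everywhere and should be treated as a tunable
  convention, not a fact about the data.

Entries are averaged per species with **equal weight per entry**; reported
sample sizes are metadata only. The indices are

    H = (Leaves + Roots + Plants + Algae) / (sum of all categories except Other)
    F = (Leaves + Plants) / (same denominator)

so 0 ≤ F ≤ H ≤ 1 always, and a species whose intake is entirely "Other"
has no defined index (it is flagged rather than silently dropped). Before
any correlation or model fitting the indices are logit-transformed; exact
0s are first replaced by the smallest non-zero index in the species set
and exact 1s by the largest non-one index (recorded in a transform
record). The substitution is global across the species set, not per
clade, because the trait is transformed once per analysis.

## Tree covariance and transforms

For a rooted tree with branch lengths (any units; ultrametricity is never
assumed), Brownian motion with rate σ² induces tip covariance
`σ² C` with `C_ij` the shared root-to-tip path length. The transforms:

* **λ** multiplies the off-diagonal of `C` (equivalently: internal-node
  depths) by λ ∈ [0, 1]; λ = 1 is BM, λ = 0 a star tree.
* **κ** raises every branch length to κ ∈ [0, 1] before path summation,
  with 0^κ := 0 and κ = 0 mapping positive branches to 1 (punctuational
  change).
* **δ** raises node depths to δ ∈ (0, 3] and rescales so the maximum tip
  depth is preserved. The rescaling keeps σ² comparable across δ; it is a
  convention (common in standard fitting tools) that must be remembered
  when comparing fitted rates across software.
* **OU** with attraction α uses the non-ultrametric tip-pair form
  `V_ij = σ²/(2α) · e^(−α d_ij) · (1 − e^(−2α C_ij))` with `d_ij` the
  patristic distance; it reduces to BM as α → 0. Some implementations
  assume ultrametric trees here; this one does not.

Branch-length rescaling and direct covariance transformation are
implemented as two routes and tested to agree.

## Model fitting and selection

All five models are Gaussian with mean `z0·1` and covariance `σ²·S(θ)`.
`z0` and `σ²` are profiled analytically at every evaluation
(`z0 = (1'S⁻¹1)⁻¹1'S⁻¹x`, `σ̂² = r'S⁻¹r/n`), so only the transform
parameter is optimized: a bounded scalar search seeded from the best of a
fixed 11-point grid (log-spaced for α ∈ [1e−8, 50]), making fits
deterministic. Flat likelihoods (e.g. λ on a star tree) are flagged as
unidentifiable rather than failed. Bounds are λ, κ ∈ [0, 1], δ ∈ (0, 3],
matching the defaults of the standard fitting tools so results are
comparable.

Model comparison uses AICc with k = 2 for BM and k = 3 otherwise. Across a
bootstrap tree sample the package reports the per-tree AICc winner, the
winner proportions, and per-model AICc mean/SD; AICc ties below 1e−6 go to
the model with fewer parameters, and non-converged fits are excluded from
the vote with a warning.

## REML ancestral states and cross-tree summaries

Reconstruction runs per tree on the λ-rescaled tree using that tree's own
fitted λ (plug-in; λ uncertainty is deliberately not propagated). The
Brownian rate is the contrasts-based REML estimator
`σ̂² = Σu²/(n−1)` (unbiased; note that some standard implementations
return an ML-normalized rate instead, so rates — not states — may differ
from theirs by ~n/(n−1)). Node states are GLS/BLUP estimates
`ẑ_a = ẑ0 + c_a'C⁻¹(x − ẑ0·1)` with
`SE² = σ̂²[d_a − c_a'C⁻¹c_a + (1 − 1'C⁻¹c_a)²/(1'C⁻¹1)]`, the last term
accounting for the estimated root mean, and 95% CIs use ±1.96 SE.

Because bootstrap trees disagree in topology, estimates are aggregated
only at clades present in every tree (strict consensus nodes, labelled
A–E). Per-clade estimates across trees are smoothed by a Gaussian kernel
(Silverman bandwidth; R's default bandwidth differs slightly, which can
shift modes by a fraction of a bandwidth) on a 512-point grid spanning the
data range ± 3 bandwidths; the mode is the grid argmax with ties broken
toward the smaller value. Reconstruction is done on the logit scale with
inverse-logit back-transformation for reporting; whether to reconstruct on
the logit or raw-proportion scale is genuinely open, so the scale is a
switch (`logit` default) rather than a hidden assumption.

## Phylogenetic signal

Blomberg's K is `(MSE0/MSE) / E_BM[MSE0/MSE]` with MSE0 the mean squared
tip deviation from the GLS mean, MSE the GLS mean squared error, and the
BM expectation the trace form `(tr C − n/1'C⁻¹1)/(n−1)`; K is invariant to
affine trait transformations. Significance is a one-tailed tip-label
permutation test on MSE (signal = smaller MSE than permuted), with the
observed value counted among the permutations; default 1000 permutations
with an explicit seed. Pagel's λ reuses the ML λ fit and tests
`2(logL(λ̂) − logL(0))` against χ²(1).

## Independent contrasts

Standard pruning recursion; contrasts are standardized by the square root
of the summed (variance-adjusted) branch lengths. The contrast sign
convention is **first-listed child minus second** in the input Newick:
plain (non-origin) correlation of contrasts is sign-dependent, so the
convention is fixed, documented, and regression-tested. Zero-length
internal branches are replaced by 1e−8 × tree height (with a warning)
before the recursion; polytomies are rejected with advice to resolve them.

Standardization is checked Garland-style: Pearson (linear trend) and
Kendall tau-b (monotone trend) correlations of |contrast| against its SD,
both at α = 0.05. On failure, branch lengths are transformed over a fixed
grid — power maps t → t^a for a = 0.1 … 1.0, then log maps
t → ln(1 + b·t)/b for b ∈ {0.1, 0.5, 1, 2, 5, 10} — and the first
transform passing both diagnostics is used; the full trail is logged. If
nothing passes, that tree/trait's contrast test is recorded as failed and
excluded from summaries rather than silently reported.

Contrast correlations are plain Pearson and Kendall tests over paired
contrasts (node pairing by descendant tip set). An origin-forced Pearson
variant is available as an option; the default is the plain test, and the
choice is recorded in the output. PGLS regression is deliberately not
offered: a regression treats the predictor as error-free, which is wrong
for a meta-analytic diet index, and the contrast correlation answers the
actual question (correlated evolutionary change).

## The synthetic study generator

`simulate_study` produces data with the statistical structure the analysis
assumes, at the scale of the motivating dataset. Defaults: 113 species (99
focal waterfowl-like + 14 landfowl-like outgroup); a 100-tree
bootstrap-like sample made from a base birth–death tree (birth 1.0, death
0.2) with lognormal branch-rate jitter (SD 0.25), per-replicate length
jitter (SD 0.10) and 3 NNI moves, with designated clades protected so they
survive into the strict consensus; logit-herbivory evolving as a λ = 0.8
process (tip SD 0.9 around a baseline of logit 0.2 ≈ −1.4); five disjoint
herbivore clades of sizes 8, 6, 5, 4, 2 shifted +4 logit units
(≈ 25 predominately herbivorous focal species); two outgroup species fixed
at H = 0.76 and 0.74 with guaranteed multi-entry quantitative records (the
reference herbivores are among the best-studied species); log10 body mass
evolving as BM (tip SD 0.38 around 10^3.05 g ≈ 1.1 kg, i.e. a natural-scale
mean near 1.7 kg), correlated with diet innovations at ρ = 0.4, with
herbivore clades +0.25 and a renamed 4-species counter-trend genus
("Tachyerella": heavy, low-H, +0.45) emulating molluscivorous steamer
ducks; diet entries per species from a truncated geometric on 1–11 (~26%
singletons, mean ≈ 3.6), each a Dirichlet draw (concentration 50) around a
composition consistent with the species' true H (herbivorous mass split
Leaves:Roots:Plants:Algae = 70:10:15:5, non-herbivorous
Seeds:Fruits:Animal = 40:10:50, 5% "Other"), 15% rendered as
frequency-of-occurrence counts and 10% as qualitative descriptor accounts.

What passing tests on this generator do show: the full pipeline recovers
the generating indices, correlations, signal levels, and consensus-node
ancestral states from entry-level data, trees included. What they do not
show: anything about literature-specific biases (method-comparability,
seasonal/geographic sampling bias, taxonomy) in real compiled data — the
generator's entries are exchangeable noise around a fixed composition,
which real entries are not.

One emergent property deserves note: because the herbivore transitions are
applied as instantaneous shifts at clade roots, the synthetic diet trait
carries a punctuational signature, and on the full synthetic study the κ
model often out-scores λ in the AICc vote even though the diffusive part
of the trait is λ-generated. Empirical herbivory change is smoother; the
λ-wins behavior is demonstrated (and reported by the acceptance script)
with traits generated under a pure λ process on a perturbed tree sample,
where λ wins 80–100% of trees.

## Numerical conventions

* Covariance factorizations use Cholesky; singular structures raise with
  the condition number reported.
* Constant traits: model fitting and signal statistics reject them;
  ancestral reconstruction returns the constant with SE 0.
* Permutation p-values use the +1 correction, so p ∈ (0, 1].
* All randomness flows through explicit seeds (`numpy.random.Generator`);
  reruns of any pipeline configuration are bit-identical.
* Problem sizes in the test-suite calibration experiments (e.g. λ recovery
  at n = 200 over 100 replicates; type-I error over 500 replicates on a
  100-tip tree) were chosen as the smallest sizes at which the sampling
  distributions of the checked statistics are comfortably narrower than
  the asserted bands.

## Known limitations

* No taxonomic name resolution; species match by exact string.
* Entries are pooled across seasons/localities (tags are kept as metadata
  only), so seasonal diet switching is averaged, not modelled.
* λ uncertainty is not propagated into ancestral CIs.
* The OU model fits a single optimum; no multi-regime OU.
* Consensus trees carry no branch lengths and are usable only for clade
  bookkeeping, by design.
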