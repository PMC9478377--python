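# Methods

## The MP-community model

A soil sample's microplastic load is treated as a community: each
particle carries a shape, a colour and a polymer type drawn from closed
vocabularies (5 shapes, 5 colours, 9 polymers; size has 4 ordered
classes but is not a community feature by default, since the community
concept is defined on shape/colour/polymer — the builder can include it
on request).  Two encodings of the community vector are supported.  In
the default *attribute-union* encoding a sample's vector counts each
attribute level separately, so each particle contributes 3 to its row
total; this is the encoding under which a single level ("black",
"rayon") can emerge as a discriminant feature, matching how such surveys
report characteristic MP types.  The *attribute-triple* encoding uses
observed (shape, colour, polymer) combinations, each particle
contributing 1.  Which encoding was used is recorded in the pipeline
config; all downstream distances default to row-wise relative abundance
precisely because union-mode row totals are a design artifact.

Abundance is reported as items per kg of dry soil:
`abundance = n_particles / soil_mass_kg`, with the survey default of
10 g of lyophilised soil per sample.  Empty samples get abundance 0 and
explicitly *undefined* (flagged, not NaN-propagated) proportion vectors.

## Statistics

**Diversity.**  "Simpson" is implemented as the Gini–Simpson index
`1 − Σpᵢ²`, bounded in [0, 1), so the MDII geometric mean
`(S_shape · S_color · S_polymer)^{1/3}` stays in [0, 1); the
inverse-Simpson variant is available behind a flag for sensitivity
analysis.  MDII of an empty sample is an error, not zero — absence of
particles is not zero diversity.  MDII can be computed per sample or on
particles pooled per region; the default is per sample, pooling is an
explicit option, since either aggregation is defensible.  Chao1 uses
the classic estimator `S_obs + f₁²/(2f₂)` and switches to the
bias-corrected `S_obs + f₁(f₁−1)/(2(f₂+1))` when no doubletons exist,
so it is always finite and ≥ S_obs.

**ANOSIM.**  All `M = n(n−1)/2` pairwise distances are ranked with
mid-ranks on ties; `R = (r̄_between − r̄_within)/(M/2)`, which is bounded
in [−1, 1].  Significance comes from relabelling: exhaustive
enumeration of all distinct label arrangements whenever there are at
most 10,000 of them (then the p-value is exact), otherwise Monte-Carlo
permutation with the add-one rule `p = (1 + hits)/(1 + n_perm)`;
default 999 permutations, and permutation counts below 99 are recorded
as a warning in the result.  Because the statistic is rank-based it is
invariant under monotone transforms of the distances.

**Mantel.**  Pearson correlation of the two condensed distance vectors
(the conventional Mantel statistic); a rank flavour (correlation of
mid-ranks) is available to match the package's otherwise nonparametric
screens.  p by simultaneous row/column permutation of the second
matrix, exhaustive when `n! ≤ 10,000`.  Surveys also report Mantel
correlations *between locations*; since the raw object pairing is
ambiguous in that reading, the package provides an explicit
`mantel_between_regions` mode that orders each region's samples by
(depth, replicate), computes Bray–Curtis among the region's replicate
profiles, and runs the standard two-matrix test on each region pair.

**LDA ordination.**  Solves `S_b v = λ (S_w + εI) v` with between/within
scatter matrices and a ridge `ε = 10⁻⁶ · trace(S_w)/d` (recorded in the
result) so the within scatter is invertible when features are collinear
— union-mode matrices always are, because each attribute block sums to
the particle count.  At most `min(k−1, d)` axes are kept; per-axis
explained variance is `λᵢ/Σλⱼ` with tiny negative eigenvalues clipped.

**LEfSe.**  Stage 1 screens every feature with Kruskal–Wallis (mid-rank
tie correction; exact enumeration for total n ≤ 8) at α = 0.05; features
constant in the *raw* counts are never discriminant.  Stage 2, for
survivors: over 30 stratified bootstrap resamples (each group resampled
with replacement, requiring ≥ 2 distinct samples per group), a
one-vs-rest regularised Fisher discriminant is fitted on the
counts-per-million scale; the discriminant weights are rescaled to the
abundance scale (`w ← w·‖μ_g − μ_rest‖/‖w‖`), a feature's effect in one
resample is `(|w_f| + |μ_g,f − μ_rest,f|)/2` for its enriched group
(argmax of group means), and the LDA score is `log₁₀(max(mean effect,
1))`.  Features pass at score ≥ 2.0.  The one-vs-all design (no
subclass structure) and the α/threshold/bootstrap defaults are the
canonical LEfSe choices; the exact effect-size scaling constants are
fixed by the regression tests, as the original tool's scaling is
under-documented.  Groups with fewer than 3 samples make the bootstrap
unreliable: the LDA stage is then skipped and the result downgraded to
the screen alone (visible as NaN scores).  Note that on community
matrices with few, high-abundance features, chance differences that
survive the screen can carry CPM-scale effect sizes above 10²; the
score threshold is therefore a ranking device, and the false-positive
rate is governed by the stage-1 screen level.

**Association screens.**  Spearman rho is Pearson on mid-ranks,
pairwise-complete per cell; cells with fewer than 4 complete pairs are
flagged not-estimable.  p is a two-sided permutation enumeration for
n ≤ 9 and the t-approximation otherwise; Benjamini–Hochberg q-values
over all estimable cells are reported *alongside* raw p rather than
replacing it — the screens such surveys publish key off raw p, and
showing both keeps that choice transparent.  The regression result
reports the signed Pearson r (for simple OLS, |r| equals the multiple
R).  Duncan's multiple range test sorts group means, compares each
range of p means against `LSR_p = q(αₚ; p, df)·√(MSE/n_h)` with
protection level `αₚ = 1 − (1−α)^{p−1}`, harmonic-mean group size for
unbalanced data, and studentized-range quantiles computed numerically
from the distribution function (verified against published critical
values to within 0.01 for p ≤ 10, df ≤ 30); the step-down rule never
declares a subrange of a non-significant range significant, which makes
the letter display order-consistent.  For k = 2 the procedure reduces
exactly to the pooled t-test decision.  The depth-contrast t-test
defaults to Welch (regional soil tables show clearly unequal variances)
with pooled mode available for strict replication of the classic
independent-samples test.

## The synthetic survey generator

The generator emulates the field design: 5 regions (SD, HE, TJ, HN,
DB) × 2 depth layers (0–20, 20–40 cm) × 3 replicate plots, 10 g of soil
per sample.  Particle counts are Poisson with mean
`λ_region,depth × mass_kg`; the per-region/depth λ table spans the
survey's printed 4,000–10,300 items/kg band with an overall mean near
6,400 (highest in HN topsoil, lowest in SD topsoil, subsoil above
topsoil in SD and HE and below it elsewhere).  An optional
gamma-mixture (negative-binomial) dispersion knob covers overdispersion,
which per-site means ± SDs alone cannot pin down.  Attributes are drawn
from per-region multinomials: a shared base composition (fiber ≈ 95%,
<0.5 mm modal size, rayon-dominant polymers, transparent/black-dominant
colours) tilted log-linearly, `p ∝ p_base·exp(δ·s)`, along fixed
per-region signature directions (black→HE, transparent→TJ,
rayon/blue/other→HN, PE→DB, none→SD) scaled by the planted community
shift δ (default 1).  A deterministic tilt was chosen over a random
Dirichlet perturbation so the planted ground truth is fully recorded in
the config rather than seed-dependent; δ = 0 makes regions exactly
exchangeable, and separation grows monotonically in δ.  A shared
subsoil tilt (more fiber-pure, darker, finer) gives all regions a
common depth block structure, which is what makes pairwise-region
Mantel correlations positive, mirroring the cross-region community
correlation such surveys report.

Covariates: soil properties are drawn per sample from region×depth
normal distributions (means/SDs follow the survey's soil table; DOC and
MBC use plausible paddy-soil values), with the C/P and N/P noise
correlated by the planted soil-ratio parameter; climate and population
are region-level constants chosen as realistic values for the five rice
regions.  The abundance–population slope β enters λ additively
(`λ += β·(pop − p̄)`), so OLS on the simulated data estimates β directly
and its analytic confidence interval has close to nominal coverage.
The OTU table draws each sample's richness as
`S₀·(1 + γ·z_abundance/2)` taxa from a shared log-normal pool
(σ = 1.5, 400 taxa, 5,000 reads), so Chao1 co-varies with MP abundance
by the planted γ; no phylum structure or other 16S realism is
attempted.

All randomness flows from one integer seed through three named
substreams (particles, covariates, OTU) derived via `SeedSequence`
spawning, so identical (config, seed) pairs give bit-identical bundles.

### What passing tests do and do not show

The generator produces independent Poisson-multinomial samples with
region-level covariate constants.  Real surveys have spatial
autocorrelation within plots, measurement error in FT-IR polymer
assignment, detection limits at small particle sizes, and covariates
measured with their own error — none of which is emulated.  Passing the
calibration and recovery suites therefore shows the *statistics* are
implemented correctly and behave nominally under the design they
assume, not that the design assumptions hold in any particular field
data set.

## Numerical and testing choices

- Exhaustive enumeration caps: 10,000 arrangements (ANOSIM) / 10,000
  permutations (Mantel); comparisons use a 10⁻¹² slack so ties count as
  hits, keeping permutation p-values conservative.
- Distance matrices are validated to 10⁻⁹ symmetry with a zero
  diagonal; TSV round-trips are exact to that tolerance.
- Null calibration runs 1,000 simulated null surveys and requires each
  test's rejection rate at α = 0.05 to lie in [0.03, 0.07] (Monte-Carlo
  SE ≈ 0.007).  Power and recovery runs use 50 surveys at 6 replicates
  (ANOSIM), 100 seeds (LEfSe planted marker) and 500 seeds (OLS
  coverage); generator-fidelity checks average 200 bundles.  Runs that
  do not exercise the OTU machinery shrink the OTU table; this changes
  nothing about the quantities under test.
- Vocabulary canonicalization lower-cases, collapses whitespace,
  normalises unicode dashes and applies a synonym map; it is idempotent.
  The permissive policy coerces unknown values in any family to the
  literal level "other" and reports a coercion count, generalising the
  colour vocabulary's catch-all; the closed-vocabulary guarantee
  therefore holds under the strict policy only.

## Known limitations

- The LEfSe effect-size scaling is a documented convention, not a
  byte-level reimplementation of the original Galaxy tool; feature
  *sets* agree in the planted-effect regime but scores are not
  comparable across tools.
- Two-way region × depth models (interaction tests) are out of scope;
  the pipeline reports one-way contrasts per stratum.
- `mantel_between_regions` requires a balanced (depth, replicate)
  layout within each region.
- Duncan letters use the harmonic-mean group size for unbalanced data,
  the standard practical approximation.
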