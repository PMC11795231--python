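# Methods

This note documents the statistical models, numerical choices and
simulation design behind `dentasym`, and what the synthetic-data checks do
and do not establish about real data.

## Shape model and alignment

A digitized tooth is a configuration of k ordered points in 2D: n_fixed
anatomical landmarks (8 for the upper first molar, 10 for the lower)
followed by 20 occlusal-outline semilandmarks. Shape is what survives the
removal of translation, scale and rotation.

**Reflection convention.** Antimeres are physical mirror images, so right
configurations are reflected about the y-axis (exact coordinate negation)
before any alignment; landmark order is anatomical and unchanged. The
package always reflects the right side; which side a study reflects is a
pure convention with no effect on FA magnitudes.

**Sliding semilandmarks.** Outline points have no point-to-point homology,
so each semilandmark may slide along the direction tangent to its outline:
the unit chord between its two outline neighbours (the outline is closed by
default; open curves use the single adjacent chord at the ends). The slid
positions minimise the thin-plate-spline bending energy of the deformation
from the current consensus shape. Because the bending energy is a quadratic
form (v' L_k v per coordinate, L_k the TPS bending-energy matrix of the
reference) and the move solves the tangent-constrained least-squares system
exactly, a sweep can never increase the energy; t = 0 is always feasible.
Convergence is geometric at realistic noise scales (≲ 0.005 of centroid
size): ≤ 5 sweeps reach a fixed point to 1e-4.

**GPA.** Partial Procrustes: configurations are centred, scaled to unit
centroid size, and rotated (proper rotations only — a reflection appearing
during alignment would silently destroy the asymmetry signal) to a running
mean, which is re-centred and renormalised each iteration. Convergence
tolerance 1e-10 on the change in the mean's sum of squares, max 100
iterations; non-convergence returns a flagged result with a warning.
Sliding and GPA are interleaved (slide → re-GPA), 3 cycles by default —
enough that a fourth cycle changes nothing at the noise scales above. All
configurations of one tooth class (both sides, all replicates) enter a
single joint GPA, because the antimere subtraction and the individual×side
ANOVA require one common shape space. The 2D optimal rotation uses the
closed form atan2(Σ x∧t, Σ x·t).

**Tangent projection.** Aligned unit-size shapes are projected
orthogonally onto the hyperplane tangent to the unit sphere at the mean:
x ↦ x + (1 − x·μ)μ. The mean maps to itself, the map is idempotent on the
plane, and tangent distance matches Procrustes distance to < 1% for
distances < 0.05 — comfortably covering dental FA, where the total shape
dispersion is a few percent of centroid size.

## Procrustes ANOVA and the permutation test

Observations are the flattened tangent vectors of every digitized
configuration, labelled (individual, side, replicate); the design must be
balanced. Sums of squares are sequential (individual → side →
individual×side) over all coordinates; with a balanced design they equal
the usual cell-mean contrasts and their order is immaterial. Degrees of
freedom are counted on the observation scale: I−1, 1, I−1, and N−2I for
error (N = 2IR). The F conventions are mixed-model (individuals random,
side fixed): F(FA) = MS(FA)/MS(error), while side and individual are tested
over MS(FA).

Significance uses residual randomization under the reduced model: for each
effect, the null model containing the preceding terms is fitted, its
residual rows permuted across all observations, added back to the null
fitted values, and the F statistic recomputed; p = (1 + #{F* ≥ F_obs}) /
(n_perm + 1), default n_perm = 999. The permutation p-values are
reproducible bit-exactly given (seed, n_perm). Under a pure-noise null the
FA test's type-I error at α = 0.05 is calibrated (the suite checks
[0.03, 0.07] over 500 simulations). A zero error mean square (e.g.
replicates copied exactly) flags the table as degenerate rather than
reporting a meaningless F.

## FA scoring

Replicates are averaged per (individual, side); the directional asymmetry
(DA) is the sample mean of left−right difference vectors; the individual FA
score is the Euclidean norm of (L − R) − DA over all coordinates. Isomere
scores (upper/lower molar) average into a composite; analyses use
z-standardised ln(composite). The log is undefined at exactly zero scores,
which only arise in degenerate simulations (zero FA and error variance);
the error message says so. Group contrasts use Welch's t with pooled-SD
Cohen's d, and a one-way fixed-effects ANOVA across sites.

## Records, prevalence, outcome models

Denominators only ever count observable units. PD severity collapses
grades {0,1} vs {2,3} at the individual level via the maximum observable
grade (monotone by construction). PNBF activity uses active-dominance: any
active lesion classes the individual active, because an unresolved process
at death is the epidemiologically meaningful state; laterality is bilateral
if any element type is affected on both sides, and unknown (not unilateral)
when contralateral sides were unobservable. Reported rates round half-up to
one decimal; full precision is retained internally.

Models are ordinary least squares on ln(age-at-death) (ages are
right-skewed and strictly positive) and maximum-likelihood binary logit.
Missing data are handled complete-case per model, mirroring how sample
sizes shrink when sex or lesion attributes are unassessable. Confidence
intervals are Wald on the coefficient scale and transformed monotonically
for effect summaries (percent change 100·(e^b − 1); odds ratio e^b), so CI
endpoint order is preserved. McFadden's pseudo-R² = 1 − lnL/lnL₀. Stepwise
selection is bidirectional on AIC from the intercept-only model — AIC keeps
selection deterministic and seed-free; a pure-noise predictor enters with
probability ≈ P(χ²₁ > 2) ≈ 0.16, which the suite verifies empirically.
Rank-deficient designs and complete separation raise errors naming the
offending term rather than returning unstable fits. Two-sided p-values, no
multiple-testing adjustment.

Site groupings for lesion models partition the four cemeteries: PNBF
contrasts the later-medieval pair {YB, WS} against {BG, SS}; the PD model
contrasts post-medieval {SS} against the medieval {BG, WS, YB}.

## Synthetic-data design

**Landmarks.** config(i, s, r) = mean + ind_i ± da/2 + fa_{i,s} +
err_{i,s,r}, all random terms isotropic Gaussian per coordinate in the mean
shape's frame, then pushed to "image space" by a random similarity
transform (and mirrored for the right side). The mean template is a regular
polygon of fixed landmarks inside a circular 20-point outline, unit
centroid size; anatomical realism is deliberately out of scope. Applying
noise in the mean's frame keeps variance components analytically tractable;
the image-space transform exercises the alignment machinery.

Default SDs are calibrated from the balanced design's expected sums of
squares so the variance decomposition matches the structure seen in real
molar data — individual ≈ 0.83 of total SS, FA ≈ 0.14, error ≈ 0.02, side
≈ 0.002. With R = 3 replicates and I = 150 individuals the target ratios
give σ_fa ≈ 3.01 σ_err and σ_ind ≈ 4.81 σ_err; σ_err = 0.002 (units of
centroid size ≈ 1) anchors the absolute scale, and the DA offset norm
0.0054 (opposite x-displacements of two fixed landmarks, so no net
translation) sets the side share. A single simulated sample at I = 150
recovers each share within ±0.04.

**Cohort.** The fitted age models use lesion presence as predictors while
the lesion models use age — a cyclic dependence no joint distribution need
satisfy. The generator therefore draws, in order: site, maturity and sex
(study-scale layout: BG 37/47, SS 14/19, WS 20/9, YB 33/37
immature/mature; mature sex frequencies 36 F / 49 M / 27 indeterminate,
with a latent coin for unassessable sex so complete-case ns shrink
realistically); lesion presence as Bernoulli at cohort prevalences (PD
0.144 immature / 0.732 mature; PNBF 0.258 / 0.304); ln(age) from the
maturity-specific linear model (immature: 2.095 + 0.176·FA + 0.460·PD, σ =
0.47; mature: 3.145 + 0.640·PNBF + 0.588·PD − 0.154·FA − 0.216·male −
0.393·PNBF·PD, σ = 0.33); PNBF activity from maturity and laterality from
FA; moderate-severe PD from age, PNBF and site among PD-present
individuals. The residual SDs were chosen so the refitted models explain
study-like variance shares (adjusted R² ≈ 0.19 immature at n≈100, ≈ 0.46
mature at n≈61). Consequently the age, activity and laterality models are
exactly generative — refitting at n = 5000 recovers every coefficient
within 2 SE, and 95% Wald CIs cover truth at study sample sizes — while
the lesion-presence-on-age models are fit-only demonstrations.

Maturity is the latent cohort label, not a hard threshold on the drawn
age: thresholding at the nominal 20-year eruption boundary would either
decouple maturity from its generating model or require truncation that
biases coefficient recovery; real dental maturity is not a strict age
cutoff either. Ages therefore overlap the boundary slightly.

**Stress linkage.** A latent standard-normal stress z_i (shifted by +0.8
for the immature cohort) scales each individual's FA noise
multiplicatively, σ_fa,i = σ_fa·exp(0.3·(z_i − z̄) − 0.3²); centring keeps
the cohort-average FA variance at the calibrated value while the shift
reproduces an immature-vs-mature composite-FA contrast of Cohen's d ≈ 0.7,
the magnitude typical of such cohort comparisons. Landmark and cohort
generation consume disjoint streams spawned from one master seed, so
outputs are bit-reproducible and independently variable.

**What the simulations do not show.** The generator's teeth are circles
around polygons, its noise is isotropic and Gaussian, missingness is
random, and the stress→FA link is exactly multiplicative. Passing recovery
tests therefore demonstrates that the estimators are correct under their
own assumptions — not that real molar FA is unbiased under taphonomic
loss, non-isotropic digitizing error, or observer drift. Those effects
need real replicated data.

## Problem sizes

Test-suite simulation sizes were chosen to keep the full suite under a
minute while leaving Monte-Carlo margins comfortable: 500 null simulations
(8 × 2 × 2 design, 199 permutations) for type-I calibration, one I = 150
sample for variance-component recovery, n = 5000 for coefficient recovery,
500 replicates at n = 100 for CI coverage. The acceptance script runs the
full study scale (154/147 pairs, 999 permutations, 216-individual cohort)
in well under a minute on one CPU.

## Known limitations

- 2D only; no reflection-permitting Procrustes; outline resampling from raw
  curves is assumed done at digitization.
- The Procrustes ANOVA requires a balanced design; individuals missing a
  side or replicate must be excluded upstream (pair_antimeres reports them).
- Wald intervals can undercover for small logistic ns; profile-likelihood
  intervals are not implemented.
- Stepwise selection inherits AIC's known false-inclusion rate; it is a
  reproduction of common practice, not a recommendation.
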