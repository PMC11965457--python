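# Methods

## Normative model

Each region of interest (ROI) is modelled independently. The measurement y
(thickness mm, area mm², or volume mm³) is mapped to a Gaussian modelling
space by an affine sinh-arcsinh (SHASH) warp

φ(y) = sinh(δ·arcsinh((y − c)/d) − ε),

which is strictly increasing for δ > 0, d > 0 and reduces to an affine map at
ε = 0, δ = 1. ε < 0 skews the implied distribution of y left, ε > 0 right;
δ < 1 gives heavier, δ > 1 lighter tails. In warped space a Bayesian linear
regression applies: φ(y) ~ N(wᵀψ(x), 1/β) with isotropic prior w ~ N(0, I/α).

The basis ψ(x) is: intercept; a cubic B-spline in age with 5 interior knots
placed at training-age quantiles (first spline column dropped — the B-spline
basis sums to one and would be collinear with the intercept); and one-hot
fixed effects for training scanner sites (first site is the reference level).
Degree and knot count are configurable (`BasisSpec`). Ages outside the
training range are allowed with a logged warning; the spline extrapolates and
the predictive variance grows, shrinking extrapolated Z-scores toward zero.

### Fitting

Hyperparameters (ε, log δ, log α, log β) maximize the type-II marginal
likelihood of the warped observations plus the Jacobian term Σ log φ′(yᵢ);
the weight posterior (mean and covariance) is closed-form given them. The
warp's affine part is anchored at the training moments, c = mean(y),
d = sd(y). We experimented with optimizing (c, d) as well: the marginal
likelihood becomes multimodal and admits sharp-warp solutions that chase
individual training points (d → 0), collapsing held-out likelihood, so the
anchored form is used. ε and log δ are box-bounded to [−2, 2] and
[log 0.3, log 3] — the mild-skew regime relevant for morphometry residuals —
which also excludes those degeneracies. Optimization is L-BFGS-B from the
identity-warp start plus 3 seeded jittered restarts, relative tolerance 1e-8;
non-convergence of all restarts raises with the optimizer traces. With
`warp_mode="identity"` the warp is frozen and the fit reduces exactly to
evidence-optimized Bayesian ridge regression (this is tested against the
closed-form solution).

### Site transfer and scoring

Sites absent from training are handled by calibration, not refitting: healthy
controls from the new site give standardized warped residuals
r = (φ(y) − wᵀψ(x))/σ_pred (site dummies zero, i.e. the reference-site
baseline), whose mean μ_s and sd ρ_s (ddof=1) define the adaptation. At least
10 calibration subjects per site are required (configurable). Deviation
scores are

Z = (φ(y) − wᵀψ(x) − μ_s·σ_pred)/(ρ_s·σ_pred),
σ_pred² = 1/β + ψ(x)ᵀ Σ_w ψ(x).

Training sites use (μ_s, ρ_s) = (0, 1). Scoring a site that is neither in
training nor adapted is an error pointing to `adapt_to_site`. Centile curves
are φ⁻¹(wᵀψ + σ_pred(μ_s + ρ_s Φ⁻¹(p))), monotone in p by construction.

Models serialize to one JSON per (modality, ROI) including adaptation
entries; a save/load round trip reproduces Z-scores bit-identically.

## Extreme-deviation maps

Thresholding is strict (Z > t, Z < −t; t = 2 by default; a score exactly at
the threshold is not extreme). Per (group, ROI, sign) the summary reports
count and percentage of group members flagged, with frequency tiers at
≥5/7.5/10%; per subject, burden counts aggregate flags across the requested
modalities (default: all three). Group mean extreme rates average each
subject's percentage of flagged regions (a pooled-flags variant is available
behind a flag; the two coincide when all subjects share the region count).
Top-k listings break ties by (percentage desc, count desc, ROI name asc).

## Inference

**Matching.** 1:1 nearest-neighbor without replacement on the linear
predictor of a logistic regression of case membership on age and site
dummies; cases processed in descending propensity order. On perfect
separation the distance falls back to a standardized-covariate projection
with a warning. Balance reports standardized mean differences (pooled-sd) for
age and each site indicator, before and after matching.

**Permutation GLM.** Outcome and regressors are demeaned (one residual df is
charged for the implicit intercept). The observed t is the OLS contrast
statistic; the null is Freedman–Lane: residualize the outcome on nuisance
regressors, permute those residuals, refit the full model. p_unc uses the
add-one estimator (1 + #{|t*| ≥ |t|})/(1 + P), two-sided by default;
`exact=True` enumerates all permutations (n ≤ 9) and returns the exhaustive
p. Tie comparisons use a relative tolerance of 1e-10 so the identity
permutation always counts. Group contrasts include age as nuisance, plus ICV
for area and volume only; subjects without ICV are excluded from those
modalities with a logged count.

**Contrast family.** The default family is 4 group pairings (each clinical
group vs HC, and SSD-V vs SSD-NV) in both directions — 8 contrasts. With
two-sided tests the two directions of a pairing give identical p-values; the
family is kept at 8 because the multiplicity-correction pool is defined over
directional contrasts. Outcomes are signed Z by default; positive/negative
deviation channels (Z clipped at zero) are a config switch.

**Multiplicity.** Benjamini–Hochberg FDR is the default, applied over three
nested pools: regions within (modality, contrast); regions × contrasts within
modality; and everything. Because BH over a wider pool can fall below a
narrower tier, reported tiers take the running maximum so they are
non-decreasing. The max-statistic (Westfall–Young) familywise alternative is
exact over regions, which share one permutation scheme; the wider tiers then
apply Bonferroni factors across contrasts and modalities, since different
contrasts involve different subject subsets and admit no common permutation.

**Burden tests.** One-sided label-permutation tests on per-subject burden
counts (statistic: difference in group means), directionally as posed:
clinical groups carry *more* negative and *fewer* positive extremes than
comparison groups. Degenerate inputs (all counts equal) return p = 1 with a
warning.

**Trait association.** Within the violence groups (PCL-R present), the PCL-R
regressor is tested per region via Freedman–Lane with age, psychosis status,
and (area/volume) ICV as nuisance; Cohen's d uses the same t-based
convention. At least 10 scored subjects are required.

**Cohen's d.** d = t·√(1/n₁ + 1/n₂) from the contrast t. For a plain
two-sample comparison this equals the classic pooled-sd d; with covariates it
is a partial-effect analogue. Published (t, d) pairs are not exactly
reproducible by any single convention, so no attempt is made to match them.

## Synthetic cohorts

The generator (`cohort_sim`) emulates the study's statistical structure: male
cohorts SSD-V (n=38), SSD-NV (n=138), nonSSD-V (n=20), HC (n=196), a healthy
reference pool across 4 training sites, and a healthy calibration pool
(default n=998) at the transfer sites. Each region follows

y = trajectory(age) + icv_term + site_offset·σ + site_scale·σ·S(η),

with S(η) = sinh((arcsinh(η) + ε)/δ) the inverse SHASH map of standard-normal
noise. Defaults, fixed as the study conditions: group age distributions are
truncated normals with moments matching such cohorts' descriptive statistics
(e.g. SSD-V 34.7 ± 8.9 years over 19.2–54.1); PCL-R totals are truncated
normals (SSD-V 18.9 ± 8.15, nonSSD-V 20.8 ± 7.84), clipped to [0, 40];
residual skew/tail (ε, δ) are (0.2, 1.1) thickness, (0.15, 1.05) area,
(0.1, 1.1) volume with σ = 0.12 mm (thickness) or 6–8% of the regional
baseline (area/volume); site offsets span ±0.25σ with scale factors 0.85–1.2,
magnitudes typical of multi-scanner harmonization studies; ICV couples to
area (r = 0.45) and volume (r = 0.35) via a loading chosen so the marginal
correlation equals the stated value absent age/site variance. Trajectories
are cubic polynomials in age with region-specific coefficients drawn from a
fixed per-region stream (independent of the cohort seed): baselines 2.1–3.1
mm / 300–2600 mm² / 700–18000 mm³ and 2–8% decline per 30 years. Sparse group
effects add a shift (in site-scaled σ units) to a Bernoulli(prevalence)
subset of a group; a trait link adds slope·(PCL-R − group mean)·σ per point.
One RNG stream per (purpose, modality) pair, all derived from the cohort seed,
so toggling effects preserves the noise realization.

What the generator does **not** emulate: spatial correlation between regions;
heteroskedasticity across age; medication or substance-use confounds;
non-SHASH outliers (a contamination switch can be added to the noise spec but
trajectories and noise are otherwise well behaved). Passing tests therefore
demonstrate correctness of the machinery under realistic-magnitude but
idealized conditions, not robustness to every property of real morphometry.

### A deliberate misspecification and its consequence

Trajectory, site offsets and site scales act in *raw measurement units*,
while the model's mean, site effects and noise live in *warped* space. The
single-warp family therefore cannot normalize the generative law exactly —
exactly as with real multi-scanner data. The consequence is quantified by the
acceptance script's calibration section: after transfer to an unseen site
(calibration n=200), held-out Z-scores are mean/sd-calibrated, but the
extreme-negative tail rate sits around 1.3–2.0% against the nominal Gaussian
2.275%, at or below the lower edge of a 99% binomial interval depending on
seed. In the correctly-specified limit (single site, flat trajectory) the
tail rate is nominal, confirming this is structural, not an implementation
artifact. Practically: extreme-deviation frequencies from moment-calibrated
site transfer are mildly conservative in the short tail of a skewed measure.

## Problem sizes

The test suite and acceptance script run scaled-down designs chosen for
statistical informativeness per unit time: reference pools of 400–1000,
calibration 120–200 per run, 6–12 regions per modality, 150–1000 permutations
(10,000 remains the library default and is one config change), 20 replicates
for recovery properties, and 500 datasets × 500 permutations for error
control. The two statistically fragile checks — the ±0.05 mean band after
n=200 calibration (sampling SE of the calibration offset alone is
1/√200 ≈ 0.07) and the requirement that a PCL-R-linked region ranks first in
≥90% of replicates (per-replicate win probability ≈ 0.85 at the stated slope
of 0.05 Z per point and n=58) — are run at fixed seeds and reported as
observed.

## Known limitations

- Tail calibration under raw-unit site scaling (above).
- Moment-only site adaptation; no refitting of weight posteriors at new sites
  and no hierarchical site model.
- Westfall–Young at the wider tiers uses Bonferroni across contrasts and
  modalities rather than a joint max-statistic.
- Region dictionary defaults to 148 + 148 + 31 = 327 regions and is fully
  configurable; analyses quoting other totals can supply their own catalog.
- Independent fits per region; no spatial regularization.
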