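# Methods

## Survival model and normalization

Viability is measured as a per-well luminescence signal; survival fractions
are treated-well signals divided by the mean of the untreated control wells
of the same stratum (model system × oxygen condition × assay day). Values
above 1 are retained — they are noise above the control mean and carry
information about the error scale. Survival after a single dose *d* follows
the linear-quadratic model S(d) = exp(−αd − βd²) with α, β ≥ 0; negative
radiosensitivity is non-physical, so the fit is constrained and a boundary
hit (α̂ = 0 or β̂ = 0) is flagged in the diagnostics rather than silently
reported as an interior estimate. When β̂ = 0 the α/β ratio is reported as
absent, not infinite.

## Fitting

The default fit domain is log-survival: −ln S is linear in (d, d²) with no
intercept, so the estimate is a deterministic non-negative least-squares
solution (NNLS) requiring no starting values. Survival fractions are
floored at 1e−6 (configurable) before the log transform; the floor only
binds when survival falls below it, far outside the published parameter
range on a 0–30 Gy grid. A bounded nonlinear fit on S itself is available
(`fit_domain="survival"`, started from the log-domain solution); the two
agree exactly on noiseless data but weight noise differently — log-domain
fitting is maximum likelihood under multiplicative lognormal error,
survival-domain under additive Gaussian error.

Fits use all replicate points rather than per-dose means by default, so the
replicate scatter informs the standard errors; per-dose-mean fitting is an
option. Standard errors and the α–β covariance come from the local
curvature of the objective, s²(XᵀWX)⁻¹ with s² = SSR/(n−2); goodness of fit
is R² = 1 − SSR/SST on the fit domain (negative values are possible and
meaningful; zero total variance raises a degenerate-fit error). The
standard error of the ratio α/β uses the delta method,
Var(r) = (σ_α/β)² + (α σ_β/β²)² − 2(α/β³)Cov(α,β); a residual bootstrap in
the log domain reproduces it within sampling error.

## OER and day averaging

Per-day α/β ratios of one arm are combined by arithmetic mean, and
OER = mean hypoxic ratio / mean normoxic ratio (`ratio_of_means`). The
alternative `mean_of_ratios` (average of day-matched quotients, requiring
identical day coverage in both arms) is retained as an option; on the
published organoid values the two give 1.3834 and 1.4458, both 1.4 at one
decimal. `ratio_of_means` is the default because it is the rule under which
the published summary values (17.7 Gy and 1.4) are jointly consistent.

## Scheme design

BED = n·d·(1 + d/(α/β)). The design stage takes a reference scheme
(default 2 Gy × 30 at α/β = 10 Gy, BED 72 Gy₁₀), multiplies each candidate
dose per fraction by the OER, and chooses the fraction count nearest to the
real-valued isoeffect solution, verifying local optimality among
neighbouring integers; a target below half of one fraction's BED is
rejected. Nearest-integer rounding (not ceiling) is used because the
isoeffect solutions land at 25.01 and 9.77 fractions for the 2.52 and
5.6 Gy schemes. Schemes carry full-precision BED internally; table
rendering rounds half-away-from-zero to integers. The estimated OER and
hypoxic α/β are applied to design at one-decimal reporting precision by
default (`design_precision_dp=1`), which is how the summary values 1.4 and
17.7 Gy yield the corrected doses 2.52 and 5.6 Gy; set it to `None` for
full precision. BEDs computed with different α/β are tagged but never
converted; `bed_ratio` warns when comparing across tags. The inverse
problem (dose per fraction for a target BED at fixed n) is the positive
root of the per-fraction quadratic and round-trips with BED to 1e−10
relative error.

## Synthetic data

The survival simulator draws each well signal as
baseline × S(d; α, β) × ε with ε mean-1 lognormal
(σ² = ln(1 + cv²), μ = −σ²/2): luminescence readouts are strictly positive
and right-skewed, and the mean-1 parameterization makes the expected
normalized survival equal S(d) exactly. Defaults follow the study
conditions: dose grid {0, 0.5, 1, 2, 4, 8, 12, 16, 20, 25, 30} Gy (the
exact published grid spans 0.2/0.5–30 Gy but was not printed in full),
3 replicate wells per dose, 3 control wells, cv = 0.10. All randomness
flows from one integer seed; identical designs and seeds give identical
tables.

Two estimator properties of the log-domain fit under this noise model are
worth stating plainly. First, E[ln ε] = −σ²/2 and the shared control-mean
normalization add a small common offset to every log-survival response;
with no intercept in the design this projects onto (d, d²) and inflates α̂
by roughly 5% at the default design sizes. The noise itself is mean-1
(tested to 3 Monte-Carlo SEs); the fit bias is a property of the estimator,
shrinks slowly with control-well count, and is dwarfed by sampling spread.
Second, because of that offset the bias of the ratio α̂/β̂ (2–5%) is below
Monte-Carlo resolution at a few hundred repeats, while its dispersion falls
cleanly with replicate count — the validation suite therefore checks exact
recovery at zero noise, strictly decreasing dispersion at 3/10/30
replicates, and a bias ceiling, rather than a monotone bias decline it
could not resolve.

The growth simulator is exponential volume growth with an instantaneous
multiplicative kill S(d) at each fraction, lengths and widths back-computed
from volume through V = L·W²/2 at a fixed aspect ratio (default
length:width = 1.3) and independently perturbed. Defaults mirror the
in-vivo study layout: 7 animals per group, treatment from ≈200 mm³,
measurements every other day, hypoxic day-21 LQ parameters. It exists to
exercise the caliper metrics with known ground truth; it models no
repopulation, repair kinetics, oxygen diffusion or immune effects, so
passing tests validate the analysis code, not NPC xenograft kinetics. The
±15% dose-rate error of a ¹³⁷Cs source is not simulated by default.

## In-vivo metrics

Tumor volume is the standard two-axis ellipsoid approximation
V = length·width²/2; entries with width > length are axis-swapped with a
warning. Growth summaries are descriptive only: relative volume versus each
animal's day-0 reading, time-to-threshold as the first *measured* day at or
above the threshold (no interpolation; measurements are every other day),
and growth delay as group mean time minus control mean. Animals never
reaching the threshold are reported censored and excluded from means, not
imputed. No significance testing is performed here.

## Problem sizes

The validation suite and the acceptance script use 120–500 simulated
experiments per Monte-Carlo check (each: 11 doses × 3 replicates + 3
controls) and 200 experiments per parameter set for recovery studies —
sizes at which the medians under study are stable to a few percent while
the full suite runs in well under a minute.

## Known limitations

- The analysis treats per-day α/β ratios as exchangeable replicates; with
  only two assay days the arm means carry substantial uncertainty that the
  OER point estimate does not reflect (a delta-method `se_oer` slot exists
  but day-to-day variation with n = 2 makes it fragile, so it is optional).
- OER is defined here as a ratio of α/β ratios, not as the classical
  isoeffect dose ratio of full survival curves; the two coincide only under
  specific parameter configurations.
- Clonogenic (colony-forming) statistics are out of scope: the target assay
  is viability-based, as colony formation is not applicable to organoids.
- Multi-fraction survival modelling with repair/repopulation terms is not
  implemented; BED arithmetic assumes complete inter-fraction repair.
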