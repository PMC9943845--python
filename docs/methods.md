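# Methods

## The model

`rverdict` models the direction-averaged DW-MRI signal of prostate tissue
as three non-exchanging water pools:

* **vascular** — water in capillaries, modelled as randomly oriented
  "sticks" with intra-stick diffusivity `D_vasc = 8 μm²/ms`; after powder
  averaging the attenuation is `√π·erf(√(b·D))/(2√(b·D))`;
* **intracellular** — water restricted in impermeable spheres of apparent
  radius `R` with `D_ic = 2 μm²/ms`, evaluated with the Gaussian-phase
  -distribution (GPD, Murday–Cotts/Balinov) closed form for a rectangular
  PGSE pair;
* **extracellular/extravascular (EES)** — isotropic Gaussian diffusion
  `exp(-b·D_ees)`.

The classic (diffusion-only) model normalises each shell by its b = 0
measurement and fits the signal fractions and radius:

    S(b)/S0 = f_vasc·S_vasc + f_ic·S_ic + f_ees·S_ees,   Σ f_i = 1

The joint relaxation–diffusion model keeps the b = 0 rows as data and
adds compartment-specific T2 decay plus a single-pool T1 saturation:

    S(b,TE,TR) = S0·(1 − e^(−TR/T1))·[ f⁰_vasc·e^(−TE/T2_vasc/ees)·S_vasc
                 + f⁰_ic·e^(−TE/T2_ic)·S_ic + f⁰_ees·e^(−TE/T2_vasc/ees)·S_ees ]

Its eight free parameters are S0, T1, T2_ic, T2_vasc/ees, f⁰_ic, f⁰_ees,
R and D_ees (free here, fixed at 2 μm²/ms in the classic model).  The
vascular fraction is always derived as `1 − f_ic − f_ees` (clipped at 0),
so the simplex constraint cannot be violated by construction.  Derived
maps: `f_vasc` and the cellularity index `f_ic/R³`.

Assumptions worth keeping in mind: no exchange between pools, no
diffusion-time dependence of the diffusivities (defensible at the
protocol's 22–36 ms effective diffusion times), a single tissue-wide T1
pool, a shared vascular/EES T2, and no explicit stroma compartment
(stroma contributes to the EES pool).

## Units and protocol

One unit system everywhere: times in ms, lengths in μm, diffusivities in
μm²/ms; b-values are stored in s/mm² and converted internally to ms/μm²
(b/1000).  The proton gyromagnetic ratio is γ = 2.6752218744·10⁵
rad·ms⁻¹·T⁻¹, used only to report the gradient amplitude G from
b = γ²G²δ²(Δ − δ/3); the sphere attenuation consumes (γG)² = b/(δ²(Δ−δ/3))
directly, which keeps the GPD expression dimensionally consistent without
touching γ.

The built-in protocol is the 10-measurement prostate VERDICT scheme: five
shells (b; δ; Δ; TE; TR) = (90; 3.9; 23.8; 50; 2482), (500; 11.4; 31.3;
65; 2482), (1500; 23.9; 43.8; 90; 2482), (2000; 14.4; 34.4; 71; 3945),
(3000; 18.9; 38.8; 80; 3349), each preceded by a b = 0 acquisition at
matched (TE, TR); 4 averages below b = 100 s/mm², 6 above.  A nonzero-b
row is paired with the nearest preceding b = 0 row with equal (TE, TR).

## Numerical choices

* **Sphere eigenvalues.** The GPD sum uses the first M = 40 roots of
  j₁'(α) = 0 (first root 2.0815759778…), found by bracketed root-finding
  with 1e−12 tolerance and cached.  Doubling M changes fixture-shell
  values by < 1e−8.
* **b = 0 rows** return attenuation 1 by definition; the formula is never
  evaluated with G = 0.
* **Direction handling.** The acquisition averages three orthogonal
  directions and all three compartments are isotropic after powder
  averaging, so the forward model is direction-free; a helper averages
  per-direction volumes for data that arrive unaveraged.
* **GPD accuracy.** The closed form was validated two ways: against an
  independent numerical evaluation of the phase-variance double integral
  (agreement ~1e−4) and against a Monte-Carlo random walk in a reflecting
  sphere.  The MC comparison exposes the intrinsic limit of the
  Gaussian-phase assumption: at the strongest shells (b = 1500–3000
  s/mm²) with R = 8–12 μm the GPD overestimates the signal by up to
  ~0.026 (absolute), far above the MC noise floor.  This is a property of
  the approximation, not of the implementation, and is shared by standard
  GPD implementations in the field.

## Estimators

* **Network.** A fully connected regressor with three hidden layers of
  256 units (ReLU), linear outputs, mean-squared-error loss on min–max
  normalised targets, Adam (lr 1e−3, batch 1000), up to 100 epochs with a
  10% validation split and early stopping; deterministic given the seed.
  "Three fully connected layers" is read as three *hidden* layers; the
  architecture is config-exposed.  Inputs: the raw 10-vector divided by
  the mean of its b = 0 rows (joint model) or the five shell-normalised
  values (classic model).  Predictions are clipped into the training
  ranges and fraction pairs renormalised onto the simplex.
* **NLLS benchmark.** Box-constrained trust-region least squares with an
  analytic Jacobian, started from the best 10 of a 3-point-per-parameter
  grid (invalid fraction pairs dropped), tolerances 1e−8, at most 100
  iterations per start.  Residuals never exceed the best grid start.
  Noiseless mid-range signals are recovered to ~1e−4 of truth.

## Synthetic data and noise

Training and evaluation signals are drawn uniformly per parameter within
the ranges below, with fraction pairs rejection-resampled onto
f⁰_ic + f⁰_ees ≤ 1 (keeping non-fraction marginals exactly uniform, at
the cost of mildly non-uniform fraction marginals):

| parameter    | range          | note                                   |
|--------------|----------------|----------------------------------------|
| S0           | 0.9 – 1.1      | scale left free around 1               |
| T1           | 500 – 5000 ms  | widened around in-vivo 1500–3000 ms    |
| T2_ic        | 10 – 150 ms    | fast pool, widened from ~40–100 ms     |
| T2_vasc/ees  | 150 – 1500 ms  | slow pool, widened from ~160–1300 ms   |
| f⁰_ic, f⁰_ees| 0.01 – 0.99    | joint sum ≤ 1                          |
| R            | 0.01 – 15 μm   |                                        |
| D_ees        | 0.5 – 3 μm²/ms |                                        |

Noise is Rician: s → √((s+n₁)² + n₂²) with σ = S0/SNR applied to the
*unnormalised* signal, SNR 35 by default (the protocol's nominal value).
The generator emulates per-voxel signal formation only — it has no
spatially correlated noise, no partial-volume mixing between regions, no
motion/eddy/Gibbs artifacts and no preprocessing residuals — so passing
tests demonstrate correctness of the estimation machinery under the
stated noise model, not robustness to everything real scanner data can do.

The realistic prostate-cancer operating point used in the degeneracy,
long-T2 and relaxation-bias experiments is T1 = 2700 ms, T2_ic = 70 ms,
T2_vasc/ees = 530 ms, f⁰_ic = f⁰_ees = 0.40, R = 8 μm, D_ees = 2 μm²/ms,
S0 = 1.

## Error conventions

Estimation error is reported as a percent of truth:
e = (est − truth)/truth·100.  Per parameter, *bias* is mean(e) and
*dispersion* is s.d.(e); pooled values are the unweighted mean over the
seven non-S0 parameters.  Samples whose truth is below 5% of the
parameter's range width are excluded from percent-of-truth statistics
(the ratio is unbounded there); range-relative moments over all samples
are reported alongside.  Fraction errors in the relaxation-bias
comparison are reported both as percent of truth and as percentage points
of fraction; the headline reduction uses percent of truth, the only
reading compatible with fraction errors larger than the feasible
absolute-error range.

Repeatability: adjusted R² from an OLS fit of scan 2 on scan 1; CV as the
per-ROI s.d./mean over the two scans averaged across ROIs; ICC for a
two-way model, absolute agreement, single measurement (ICC(A,1));
Bland–Altman mean difference with ±1.96 s.d. limits.  Group differences:
one-way ANOVA followed by pairwise t-tests with Bonferroni correction,
significance at corrected p < 0.05.  T2 distributions are compared with a
two-sided Wilcoxon rank-sum test plus medians and IQRs.

## Problem sizes

The acceptance script trains on 10⁵ signals and evaluates the network on
10⁴ test signals, NLLS on 10³ of the same signals, 50 noisy repeats per
long-T2 grid point and 2000 repeats for the relaxation-bias comparison.
The test suite uses smaller session-scoped estimators (4·10⁴ training
signals) and NLLS subsets of 100–150 voxel fits per experiment; the
Monte-Carlo oracle uses 10⁵ walkers per shell.

## Known limitations

* The GPD sphere signal departs from the true restricted-diffusion signal
  at the strongest shells (see above); estimates inherit that model error.
* With the protocol's maximal TE of 90 ms, the long T2_vasc/ees is weakly
  identified: a minimum-MSE estimator trained over the full prior range
  regresses towards the prior mean, so signed errors at the extremes of
  the 150–1500 ms range are large even though dispersion is modest.  The
  long-T2 experiment quantifies exactly this.
* Pooled bias/dispersion numbers depend strongly on the sampled parameter
  ranges and on the percent-of-truth convention; with the wide ranges
  above, small-truth samples dominate the dispersion of fraction, radius
  and T2 errors.
* The NLLS benchmark, as in common practice, is sensitive to local minima
  and bound saturation at low SNR; its dispersion should be read as a
  property of the (objective, starts) combination, not of least squares
  in the abstract.
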