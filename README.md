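# rverdict

Joint relaxation–diffusion microstructure modelling of prostate DW-MRI.

Quantitative prostate MRI models such as VERDICT decompose the
diffusion-weighted signal into vascular, intracellular and
extracellular/extravascular water pools, yielding maps — intracellular
fraction f_ic, apparent cell radius R, cellularity f_ic/R³ — that track
Gleason grade better than the ADC.  Because each pool also has its own T2
(and the tissue a T1), fractions fitted from diffusion alone are biased
by relaxation weighting.  This package implements the relaxation-aware
extension: a forward model

S(b, TE, TR) = S0·(1 − e^(−TR/T1))·[ f⁰_vasc·e^(−TE/T2_vasc/ees)·S_vasc(D_vasc, b)
               + f⁰_ic·e^(−TE/T2_ic)·S_ic(D_ic, R, b) + f⁰_ees·e^(−TE/T2_vasc/ees)·S_ees(D_ees, b) ]

with powder-averaged sticks for the vascular pool, Gaussian-phase
restricted spheres for the intracellular pool and a Gaussian ball for the
EES, fitted voxel-wise to the 10-measurement PGSE protocol (five shells,
each with a matched-(TE, TR) b = 0 image).  It is intended for
researchers in quantitative diffusion MRI who want the forward models,
the fast neural-network estimator and its nonlinear-least-squares
benchmark, the simulation experiments that characterise them, and the
scan–rescan / group statistics used in such studies.

What's inside:

* `protocol` — PGSE scheme representation, validation, I/O, and the
  built-in 10-measurement prostate protocol (`innovate_scheme()`);
* `compartments` / `models` — closed-form compartment signals and the
  diffusion-only and relaxation–diffusion forward models;
* `simulate` — Rician-noisy synthetic signals, training sets, degeneracy
  grids, image phantoms;
* `fit_dnn` / `fit_nlls` — a three-hidden-layer network estimator and a
  grid-initialised box-constrained least-squares benchmark (analytic
  Jacobian);
* `evaluation` — bias/dispersion, degeneracy, long-T2 accuracy,
  relaxation-bias comparison, repeatability (R², CV, ICC, Bland–Altman),
  ANOVA + Bonferroni group comparison, rank-sum distribution tests;
* `maps` — voxel-wise fitting of 4-D NIfTI volumes into parametric maps
  with ROI summaries; `rverdict` CLI for the common operations.

## Worked example

Train the estimator on synthetic signals from the built-in protocol,
then fit a noisy phantom:

```python
import numpy as np
import rverdict as rv

scheme = rv.innovate_scheme()                    # 10 PGSE measurements
ts = rv.sample_training_set(rv.DEFAULT_RANGES, scheme, 100_000, snr=35, seed=1)
est = rv.train(ts, rv.DnnHyperparams(), seed=1)

tumour = rv.RVerdictParams(s0=1.0, t1=2700, t2_ic=70, t2_vasc_ees=530,
                           f0_ic=0.40, f0_ees=0.40, r=8.0, d_ees=2.0)
mask = np.ones((8, 8, 2), bool)
img, truth = rv.make_phantom((8, 8, 2), [(mask, tumour)], scheme, snr=35, seed=2)
maps = rv.fit_image(img, scheme, est, mask)
for name in ("f0_ic", "r", "t2_ic", "f_vasc", "cellularity"):
    print(f"{name:12s} {np.nanmedian(maps[name]):8.4f}")
```

prints (median over the 128 voxels):

```
f0_ic          0.2932
r              8.7036
t2_ic         77.2778
f_vasc         0.3603
cellularity    0.0004
```

The apparent radius and intracellular T2 come back close to the
generating values (8 μm, 70 ms).  The fraction estimates show the
shrinkage typical of a minimum-MSE estimator at SNR 35: at this operating
point the relaxation–diffusion trade-off leaves the split between f⁰_ic
and the derived f⁰_vasc only weakly identified, so the network pulls
f⁰_ic (truth 0.40) down and f⁰_vasc (truth 0.20) up — the degeneracy and
bias experiments in `evaluation` quantify exactly this behaviour, and the
same experiment shows the nonlinear-least-squares benchmark scatters
considerably more.  The same estimator applied to a real direction-averaged
4-D NIfTI volume is one call (`rv.fit_image`) or one CLI invocation
(`rverdict fit-image --image dwi.nii --estimator est.joblib --out maps/`).

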