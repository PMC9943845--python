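"""Synthetic-signal generation: noise, training sets, grids, phantoms.

The estimators in this package are trained and benchmarked entirely on
synthetic signals from the forward models, mirroring how the voxel-wise
estimator is deployed on scanner data: parameters drawn uniformly over
biophysically plausible ranges, signals computed on the acquisition scheme
and corrupted with Rician noise at the protocol's nominal SNR (35, i.e.
sigma = S0/35 on the unnormalised signal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .models import (
    RVERDICT_PARAM_NAMES,
    RVerdictParams,
    rverdict_signal_matrix,
)
from .protocol import AcquisitionScheme

__all__ = [
    "DEFAULT_RANGES",
    "DEFAULT_SNR",
    "ParameterRanges",
    "TrainingSet",
    "add_rician_noise",
    "sample_training_set",
    "degeneracy_grid",
    "make_phantom",
]

#: Nominal protocol SNR (b = 0 signal over noise s.d.).
DEFAULT_SNR = 35.0


@dataclass(frozen=True)
class ParameterRanges:
    """Lower/upper bounds per free rVERDICT parameter.

    Defaults span the biophysically plausible prostate envelope: a fast
    (intracellular) T2 pool around 40–100 ms and a slow (vascular/EES)
    pool around 160–1300 ms, both widened; T1 widened around the in vivo
    1500–3000 ms range.  Fraction bounds apply marginally, with the joint
    simplex constraint f0_ic + f0_ees <= 1 enforced at sampling time.
    """

    s0: tuple[float, float] = (0.9, 1.1)
    t1: tuple[float, float] = (500.0, 5000.0)
    t2_ic: tuple[float, float] = (10.0, 150.0)
    t2_vasc_ees: tuple[float, float] = (150.0, 1500.0)
    f0_ic: tuple[float, float] = (0.01, 0.99)
    f0_ees: tuple[float, float] = (0.01, 0.99)
    r: tuple[float, float] = (0.01, 15.0)
    d_ees: tuple[float, float] = (0.5, 3.0)

    def __post_init__(self) -> None:
        for name in RVERDICT_PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: need lower < upper, got ({lo}, {hi})")
        for name in ("f0_ic", "f0_ees"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi > 1:
                raise ValueError(f"{name}: fraction bounds must lie in [0, 1]")

    @property
    def lower(self) -> np.ndarray:
        return np.array([getattr(self, n)[0] for n in RVERDICT_PARAM_NAMES])

    @property
    def upper(self) -> np.ndarray:
        return np.array([getattr(self, n)[1] for n in RVERDICT_PARAM_NAMES])

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


DEFAULT_RANGES = ParameterRanges()


@dataclass
class TrainingSet:
    """Matched (noisy signal, ground-truth parameter) matrices."""

    signals: np.ndarray          # (n, K)
    targets: np.ndarray          # (n, 8), RVERDICT_PARAM_NAMES order
    scheme: AcquisitionScheme
    snr: float
    seed: int
    ranges: ParameterRanges = field(default_factory=ParameterRanges)

    def __post_init__(self) -> None:
        if self.signals.shape[0] != self.targets.shape[0]:
            raise ValueError("signals/targets row counts differ")
        if np.any(self.signals < 0):
            raise ValueError("signals must be nonnegative")

    @property
    def n(self) -> int:
        return self.signals.shape[0]


def add_rician_noise(signal, sigma: float, seed=None) -> np.ndarray:
    """Rician-corrupt a signal: s → sqrt((s + n1)² + n2²), n ~ N(0, sigma²).

    ``seed`` may be an int or a ``numpy.random.Generator``; sigma = 0 is
    the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    s = np.asarray(signal, dtype=float)
    if sigma == 0:
        return s.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, s.shape)
    n2 = rng.normal(0.0, sigma, s.shape)
    return np.sqrt((s + n1) ** 2 + n2**2)


def sample_parameters(ranges: ParameterRanges, n: int, rng) -> np.ndarray:
    """Uniform parameter draws with simplex rejection on the fractions.

    Each parameter is drawn uniformly within its bounds; draws with
    f0_ic + f0_ees > 1 have the fraction *pair* redrawn until valid (so
    non-fraction marginals stay exactly uniform).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = ranges.lower, ranges.upper
    p = rng.uniform(lo, hi, size=(n, len(lo)))
    i_ic = RVERDICT_PARAM_NAMES.index("f0_ic")
    i_ees = RVERDICT_PARAM_NAMES.index("f0_ees")
    bad = p[:, i_ic] + p[:, i_ees] > 1.0
    while np.any(bad):
        k = int(bad.sum())
        p[bad, i_ic] = rng.uniform(lo[i_ic], hi[i_ic], k)
        p[bad, i_ees] = rng.uniform(lo[i_ees], hi[i_ees], k)
        bad = p[:, i_ic] + p[:, i_ees] > 1.0
    return p


def sample_training_set(
    ranges: ParameterRanges,
    scheme: AcquisitionScheme,
    n: int,
    snr: float = DEFAULT_SNR,
    seed: int = 0,
) -> TrainingSet:
    """Simulate ``n`` Rician-noisy rVERDICT signals with known truths.

    Noise s.d. is sigma = s0/snr applied per-draw to the unnormalised
    signal (snr = inf or 0-noise is allowed for noiseless sets).
    """
    rng = np.random.default_rng(seed)
    targets = sample_parameters(ranges, n, rng)
    clean = rverdict_signal_matrix(targets, scheme)
    sigma = targets[:, 0:1] / snr if np.isfinite(snr) else np.zeros((n, 1))
    n1 = rng.normal(0.0, 1.0, clean.shape) * sigma
    n2 = rng.normal(0.0, 1.0, clean.shape) * sigma
    noisy = np.sqrt((clean + n1) ** 2 + n2**2)
    return TrainingSet(noisy, targets, scheme, snr, seed, ranges)


def sample_verdict_training_set(
    ranges: ParameterRanges,
    scheme: AcquisitionScheme,
    n: int,
    snr: float = DEFAULT_SNR,
    seed: int = 0,
):
    """Simulate classic-VERDICT training data (relaxation-free model).

    Parameters (f_ic, f_ees, R) are drawn uniformly (fraction pair
    rejection-sampled onto the simplex); the clean signal over all scheme
    rows has value 1 on b = 0 rows and the three-compartment attenuation
    on shells, and Rician noise with sigma = 1/snr is added to the raw
    vector before any shell normalisation.  Returns (signals, targets).
    """
    from .models import verdict_signal_matrix

    rng = np.random.default_rng(seed)
    full = sample_parameters(ranges, n, rng)
    i_ic = RVERDICT_PARAM_NAMES.index("f0_ic")
    i_ees = RVERDICT_PARAM_NAMES.index("f0_ees")
    i_r = RVERDICT_PARAM_NAMES.index("r")
    targets = full[:, [i_ic, i_ees, i_r]]
    clean = np.ones((n, len(scheme)))
    clean[:, scheme.nonzero_indices] = verdict_signal_matrix(targets, scheme)
    if np.isfinite(snr):
        signals = add_rician_noise(clean, 1.0 / snr, rng)
    else:
        signals = clean
    return signals, targets


def save_training_set(ts: TrainingSet, path) -> None:
    """Persist a training set as an .npz plus a JSON metadata sidecar."""
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz",
             signals=ts.signals, targets=ts.targets)
    meta = {
        "snr": ts.snr,
        "seed": ts.seed,
        "ranges": {n: list(getattr(ts.ranges, n)) for n in RVERDICT_PARAM_NAMES},
        "scheme": ts.scheme.to_frame().to_dict(orient="list"),
        "scheme_name": ts.scheme.name,
    }
    with open((path[:-4] if path.endswith(".npz") else path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_training_set(path) -> TrainingSet:
    """Load a training set written by :func:`save_training_set`."""
    from .protocol import AcquisitionScheme, Measurement

    path = str(path)
    stem = path[:-4] if path.endswith(".npz") else path
    arrays = np.load(stem + ".npz")
    with open(stem + ".json") as fh:
        meta = json.load(fh)
    cols = meta["scheme"]
    scheme = AcquisitionScheme(
        [
            Measurement(b, d, D, te, tr, int(nav))
            for b, d, D, te, tr, nav in zip(
                cols["b"], cols["delta"], cols["Delta"],
                cols["te"], cols["tr"], cols["naverages"],
            )
        ],
        name=meta.get("scheme_name", ""),
    )
    ranges = ParameterRanges(**{k: tuple(v) for k, v in meta["ranges"].items()})
    return TrainingSet(
        arrays["signals"], arrays["targets"], scheme,
        meta["snr"], meta["seed"], ranges,
    )


def degeneracy_grid(
    fixed_point: RVerdictParams,
    ranges: ParameterRanges = DEFAULT_RANGES,
    levels: int = 4,
) -> dict[str, np.ndarray]:
    """Parameter grids probing fit degeneracy around an operating point.

    For each of the 7 non-S0 parameters in turn, that parameter is held at
    its ``fixed_point`` value while the other six take ``levels`` linearly
    spaced values within their ranges — ``levels**6`` combinations per held
    parameter.  S0 is fixed to 1 throughout.  Fraction pairs exceeding the
    simplex are rescaled onto f0_ic + f0_ees = 1.

    Returns a mapping held-parameter-name → (levels**6, 8) array.
    """
    names = [n for n in RVERDICT_PARAM_NAMES if n != "s0"]
    out: dict[str, np.ndarray] = {}
    fp = fixed_point.to_array()
    for held in names:
        varied = [n for n in names if n != held]
        axes = [
            np.linspace(*getattr(ranges, n), levels) if levels > 1
            else np.array([fp[RVERDICT_PARAM_NAMES.index(n)]])
            for n in varied
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        combos = np.stack([m.ravel() for m in mesh], axis=1)
        grid = np.empty((combos.shape[0], len(RVERDICT_PARAM_NAMES)))
        grid[:, 0] = 1.0  # S0 fixed
        grid[:, RVERDICT_PARAM_NAMES.index(held)] = fp[RVERDICT_PARAM_NAMES.index(held)]
        for j, n in enumerate(varied):
            grid[:, RVERDICT_PARAM_NAMES.index(n)] = combos[:, j]
        i_ic = RVERDICT_PARAM_NAMES.index("f0_ic")
        i_ees = RVERDICT_PARAM_NAMES.index("f0_ees")
        fsum = grid[:, i_ic] + grid[:, i_ees]
        over = fsum > 1.0
        if held == "f0_ic":
            # never move the held parameter: cap the varied fraction instead
            grid[over, i_ees] = 1.0 - grid[over, i_ic]
        elif held == "f0_ees":
            grid[over, i_ic] = 1.0 - grid[over, i_ees]
        else:
            grid[over, i_ic] /= fsum[over]
            grid[over, i_ees] /= fsum[over]
        out[held] = grid
    return out


def make_phantom(
    shape: tuple[int, int, int],
    region_params: list[tuple[np.ndarray, RVerdictParams]],
    scheme: AcquisitionScheme,
    snr: float = DEFAULT_SNR,
    seed: int = 0,
):
    """Synthetic 4-D image volume with piecewise-constant tissue regions.

    ``region_params`` is a list of (boolean 3-D mask, parameters); masks
    must be pairwise disjoint.  Returns ``(image, truth)`` where ``image``
    is (x, y, z, K) with one volume per scheme row (background zero) and
    ``truth`` maps parameter name → 3-D volume (NaN outside regions).
    """
    rng = np.random.default_rng(seed)
    k = len(scheme)
    image = np.zeros(shape + (k,), dtype=float)
    truth = {n: np.full(shape, np.nan) for n in RVERDICT_PARAM_NAMES}
    occupied = np.zeros(shape, dtype=bool)
    for mask, params in region_params:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask shape does not match phantom shape")
        if np.any(mask & occupied):
            raise ValueError("region masks overlap")
        occupied |= mask
        clean = rverdict_signal_matrix(params.to_array()[None, :], scheme)[0]
        nvox = int(mask.sum())
        sig = np.tile(clean, (nvox, 1))
        if np.isfinite(snr) and snr > 0:
            sigma = params.s0 / snr
            sig = add_rician_noise(sig, sigma, rng)
        image[mask] = sig
        for name in RVERDICT_PARAM_NAMES:
            truth[name][mask] = getattr(params, name)
    return image, truth
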