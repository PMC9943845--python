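"""VERDICT and rVERDICT forward signal models.

VERDICT expresses the direction-averaged DW-MRI signal of prostate tissue
as a three-compartment mixture::

    S(b)/S0 = f_vasc S_vasc(D_vasc, b) + f_ic S_ic(D_ic, R, b)
              + f_ees S_ees(D_ees, b),      f_vasc + f_ic + f_ees = 1

with fixed diffusivities D_ic = 2, D_vasc = 8 μm²/ms (D_ees = 2 in the
classic model).  rVERDICT adds compartment-specific T2 decay and a single
whole-tissue T1 saturation factor, so the unnormalised signal over *all*
measurements (b = 0 rows included) is::

    S(b, TE, TR) = S0 (1 − e^{−TR/T1}) [ f⁰_vasc e^{−TE/T2_vasc/ees} S_vasc
                   + f⁰_ic e^{−TE/T2_ic} S_ic + f⁰_ees e^{−TE/T2_vasc/ees} S_ees ]

where the f⁰ fractions are relaxation-unbiased and D_ees is free.  The
vascular fraction is always *derived* (1 − f_ic − f_ees), never stored, so
the simplex constraint cannot be violated.

Eight free rVERDICT parameters, in the canonical package-wide order
``RVERDICT_PARAM_NAMES``: S0, T1, T2_ic, T2_vasc/ees, f0_ic, f0_ees, R,
D_ees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import compartments as cmp
from .protocol import AcquisitionScheme

__all__ = [
    "D_IC",
    "D_VASC",
    "D_EES_FIXED",
    "RVERDICT_PARAM_NAMES",
    "VERDICT_PARAM_NAMES",
    "VerdictParams",
    "RVerdictParams",
    "verdict_signal",
    "rverdict_signal",
    "verdict_signal_matrix",
    "rverdict_signal_matrix",
    "derived_fvasc",
    "derived_cellularity",
]

#: Fixed intracellular diffusivity, μm²/ms.
D_IC = 2.0
#: Fixed intra-stick (pseudo-vascular) diffusivity, μm²/ms.
D_VASC = 8.0
#: Fixed EES diffusivity in the classic model, μm²/ms.
D_EES_FIXED = 2.0

RVERDICT_PARAM_NAMES = ("s0", "t1", "t2_ic", "t2_vasc_ees", "f0_ic", "f0_ees", "r", "d_ees")
VERDICT_PARAM_NAMES = ("f_ic", "f_ees", "r")


def _check_fractions(f_ic: float, f_ees: float) -> None:
    if not (0.0 <= f_ic <= 1.0 and 0.0 <= f_ees <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if f_ic + f_ees > 1.0 + 1e-12:
        raise ValueError(f"fraction sum {f_ic + f_ees} exceeds 1")


@dataclass(frozen=True)
class VerdictParams:
    """Classic VERDICT parameters (f_vasc derived as 1 − f_ic − f_ees)."""

    f_ic: float
    f_ees: float
    r: float
    d_ees: float = D_EES_FIXED

    def __post_init__(self) -> None:
        _check_fractions(self.f_ic, self.f_ees)
        if self.r <= 0:
            raise ValueError("R must be positive")

    @property
    def f_vasc(self) -> float:
        return derived_fvasc(self.f_ic, self.f_ees)

    @property
    def cellularity(self) -> float:
        return derived_cellularity(self.f_ic, self.r)


@dataclass(frozen=True)
class RVerdictParams:
    """rVERDICT parameters: relaxation times plus unbiased fractions.

    ``s0`` is the signal at (b = 0, TE = 0, TR = ∞); ``t1`` a single
    whole-tissue pool; ``t2_ic`` and ``t2_vasc_ees`` the intracellular and
    shared vascular/EES T2 times (ms).
    """

    s0: float
    t1: float
    t2_ic: float
    t2_vasc_ees: float
    f0_ic: float
    f0_ees: float
    r: float
    d_ees: float

    def __post_init__(self) -> None:
        _check_fractions(self.f0_ic, self.f0_ees)
        if min(self.s0, self.t1, self.t2_ic, self.t2_vasc_ees, self.r, self.d_ees) <= 0:
            raise ValueError("S0, T1, T2s, R and D_ees must be positive")

    @property
    def f0_vasc(self) -> float:
        return derived_fvasc(self.f0_ic, self.f0_ees)

    @property
    def cellularity(self) -> float:
        return derived_cellularity(self.f0_ic, self.r)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RVERDICT_PARAM_NAMES])

    @classmethod
    def from_array(cls, a) -> "RVerdictParams":
        return cls(**dict(zip(RVERDICT_PARAM_NAMES, np.asarray(a, dtype=float))))


def derived_fvasc(f_ic, f_ees):
    """Vascular fraction 1 − f_ic − f_ees, clipped to [0, 1]."""
    return np.clip(1.0 - np.asarray(f_ic, dtype=float) - f_ees, 0.0, 1.0)


def derived_cellularity(f_ic, r):
    """Cellularity index f_ic / R³ (μm⁻³), ∝ cell number density."""
    return np.asarray(f_ic, dtype=float) / np.asarray(r, dtype=float) ** 3


# ---------------------------------------------------------------------------
# forward models (vectorised over parameter sets)
# ---------------------------------------------------------------------------

def verdict_signal_matrix(params: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Normalised VERDICT signals for ``params`` rows (f_ic, f_ees, R).

    Returns an (n, n_shells) matrix over the *nonzero-b* rows of ``scheme``.
    An optional 4th column supplies per-row D_ees (defaults to 2 μm²/ms).
    """
    p = np.atleast_2d(np.asarray(params, dtype=float))
    f_ic, f_ees, r = p[:, 0:1], p[:, 1:2], p[:, 2:3]
    d_ees = p[:, 3:4] if p.shape[1] > 3 else np.full_like(r, D_EES_FIXED)
    f_vasc = derived_fvasc(f_ic, f_ees)
    idx = scheme.nonzero_indices
    b = scheme.b_internal[idx][None, :]
    delta = scheme.delta[idx][None, :]
    Delta = scheme.Delta[idx][None, :]
    s_stick = cmp.signal_stick_powder(b, D_VASC)
    s_sphere = cmp.sphere_gpd_attenuation(b, delta, Delta, r, D_IC)
    s_ees = np.exp(-b * d_ees)
    return f_vasc * s_stick + f_ic * s_sphere + f_ees * s_ees


def rverdict_signal_matrix(params: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Unnormalised rVERDICT signals for parameter rows in canonical order.

    ``params`` is (n, 8) ordered as ``RVERDICT_PARAM_NAMES``; returns
    (n, K) over *all* K rows of ``scheme`` (compartment attenuations are 1
    on the b = 0 rows).
    """
    p = np.atleast_2d(np.asarray(params, dtype=float))
    s0, t1, t2_ic, t2_ve = p[:, 0:1], p[:, 1:2], p[:, 2:3], p[:, 3:4]
    f0_ic, f0_ees, r, d_ees = p[:, 4:5], p[:, 5:6], p[:, 6:7], p[:, 7:8]
    f0_vasc = derived_fvasc(f0_ic, f0_ees)
    b = scheme.b_internal[None, :]
    delta = scheme.delta[None, :]
    Delta = scheme.Delta[None, :]
    te = scheme.te[None, :]
    tr = scheme.tr[None, :]
    s_stick = cmp.signal_stick_powder(b, D_VASC) * np.ones_like(r)
    s_sphere = cmp.sphere_gpd_attenuation(b, delta, Delta, r, D_IC)
    s_ees = np.exp(-b * d_ees)
    w_ve = np.exp(-te / t2_ve)
    w_ic = np.exp(-te / t2_ic)
    sat = 1.0 - np.exp(-tr / t1)
    return s0 * sat * (
        f0_vasc * w_ve * s_stick + f0_ic * w_ic * s_sphere + f0_ees * w_ve * s_ees
    )


def verdict_signal(p: VerdictParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Normalised VERDICT signal over the nonzero-b rows of ``scheme``."""
    return verdict_signal_matrix(
        np.array([[p.f_ic, p.f_ees, p.r, p.d_ees]]), scheme
    )[0]


def rverdict_signal(p: RVerdictParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Unnormalised rVERDICT signal over all rows of ``scheme``."""
    return rverdict_signal_matrix(p.to_array()[None, :], scheme)[0]
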