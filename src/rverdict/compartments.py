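"""Closed-form compartment signal models.

Three orientationally isotropic (or powder-averaged) compartments make up
the tissue model:

* **ball** — isotropic Gaussian diffusion, for extracellular–extravascular
  water: ``exp(-b D_ees)``;
* **powder-averaged stick** — randomly oriented capillary segments carrying
  pseudo-diffusing vascular water: the orientational average of
  ``exp(-b D cos²θ)``, which has the closed form
  ``√π erf(√(bD)) / (2 √(bD))``;
* **sphere (GPD)** — water restricted inside an impermeable sphere of
  radius R, evaluated under the Gaussian phase distribution (Murday–Cotts /
  Balinov) approximation for a rectangular PGSE pair.

All functions work in the internal unit system (b in ms/μm², D in μm²/ms,
times ms, lengths μm) and broadcast over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, spherical_jn

from .protocol import Measurement, effective_diffusion_time

__all__ = [
    "SphereContext",
    "sphere_bessel_roots",
    "signal_ees",
    "signal_stick_powder",
    "signal_sphere_gpd",
    "sphere_gpd_attenuation",
]


def _j1prime(x: float) -> float:
    return spherical_jn(1, x, derivative=True)


@lru_cache(maxsize=8)
def sphere_bessel_roots(m: int = 40) -> np.ndarray:
    """First ``m`` positive roots of j₁'(α) = 0.

    These are the eigenvalue constants of diffusion in an impermeable
    sphere (first root ≈ 2.0815759938).  Found by bracketed root-finding
    on a fine grid; the roots are asymptotically π apart.
    """
    xs = np.linspace(1e-3, (m + 2) * np.pi, int((m + 2) * np.pi * 200))
    vals = spherical_jn(1, xs, derivative=True)
    sign_change = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    roots = []
    for i in sign_change:
        r = brentq(_j1prime, xs[i], xs[i + 1], xtol=1e-12)
        if r > 1e-6:
            roots.append(r)
        if len(roots) == m:
            break
    if len(roots) < m:  # pragma: no cover - grid is generous
        raise RuntimeError(f"found only {len(roots)} of {m} roots")
    return np.asarray(roots)


@dataclass(frozen=True)
class SphereContext:
    """Cached eigenvalue roots for the restricted-sphere GPD signal."""

    bessel_roots: np.ndarray = field(default_factory=sphere_bessel_roots)

    def __post_init__(self) -> None:
        r = self.bessel_roots
        if r.ndim != 1 or len(r) == 0 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("roots must be a strictly increasing positive 1-D array")

    @property
    def m(self) -> int:
        return len(self.bessel_roots)


_DEFAULT_CTX = None


def default_sphere_context() -> SphereContext:
    global _DEFAULT_CTX
    if _DEFAULT_CTX is None:
        _DEFAULT_CTX = SphereContext()
    return _DEFAULT_CTX


def signal_ees(b, d_ees):
    """Isotropic Gaussian ('ball') attenuation exp(-b·D).

    ``b`` in ms/μm², ``d_ees`` in μm²/ms.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0) or np.any(np.asarray(d_ees) <= 0):
        raise ValueError("need b >= 0 and D > 0")
    return np.exp(-b * d_ees)


def signal_stick_powder(b, d_vasc):
    """Powder-averaged stick attenuation √π erf(√(bD)) / (2√(bD)).

    Continuous at b = 0 where the value is 1.  ``b`` in ms/μm².
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0) or np.any(np.asarray(d_vasc) <= 0):
        raise ValueError("need b >= 0 and D > 0")
    bd = b * d_vasc
    out = np.ones_like(bd)
    nz = bd > 0
    sq = np.sqrt(bd[nz]) if bd.ndim else np.sqrt(bd) if bd > 0 else None
    if bd.ndim:
        out[nz] = 0.5 * np.sqrt(np.pi) * erf(np.sqrt(bd[nz])) / np.sqrt(bd[nz])
        return out
    if bd == 0:
        return 1.0
    return float(0.5 * np.sqrt(np.pi) * erf(sq) / sq)


def sphere_gpd_attenuation(b, delta, Delta, radius, d_ic, roots=None):
    """GPD attenuation for restricted diffusion in an impermeable sphere.

    Implements the Murday–Cotts/Balinov expression for a rectangular PGSE
    pair of duration ``delta`` and separation ``Delta``::

        -ln S = (2 γ²G² / D) Σ_m  a_m⁻⁴ / (α_m² − 2)
                 · [ 2δ − (2 + e^{-a²D(Δ−δ)} − 2e^{-a²Dδ}
                            − 2e^{-a²DΔ} + e^{-a²D(Δ+δ)}) / (a²D) ]

    with a_m = α_m / R and γ²G² = b / (δ²(Δ − δ/3)) eliminated in favour of
    b (ms/μm²).  Broadcasts over all arguments; b = 0 gives exactly 1.

    Parameters
    ----------
    b : array_like
        Diffusion weighting, ms/μm².
    delta, Delta : array_like
        Pulse duration and separation, ms.
    radius : array_like
        Sphere radius, μm.
    d_ic : array_like
        Intra-sphere diffusivity, μm²/ms.
    roots : ndarray, optional
        Eigenvalue roots α_m; defaults to the cached 40-root set.
    """
    if roots is None:
        roots = default_sphere_context().bessel_roots
    b, delta, Delta, radius, d_ic = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (b, delta, Delta, radius, d_ic))
    )
    if np.any(radius <= 0) or np.any(d_ic <= 0):
        raise ValueError("need R > 0 and D > 0")
    shape = b.shape
    bf = b.reshape(-1, 1)
    df = delta.reshape(-1, 1)
    Df = Delta.reshape(-1, 1)
    rf = radius.reshape(-1, 1)
    dcf = d_ic.reshape(-1, 1)
    alpha = roots.reshape(1, -1)

    a = alpha / rf                      # 1/μm
    a2d = a**2 * dcf                    # 1/ms
    gg2 = bf / (df**2 * (Df - df / 3.0))  # (γG)², 1/(μm² ms²)
    bracket = 2.0 * df - (
        2.0
        + np.exp(-a2d * (Df - df))
        - 2.0 * np.exp(-a2d * df)
        - 2.0 * np.exp(-a2d * Df)
        + np.exp(-a2d * (Df + df))
    ) / a2d
    terms = bracket / (a**4 * (alpha**2 - 2.0))
    log_s = -(2.0 * gg2 / dcf) * np.sum(terms, axis=1, keepdims=True)
    out = np.exp(log_s[:, 0])
    out = np.where(bf[:, 0] == 0.0, 1.0, out)
    out = out.reshape(shape)
    return float(out) if out.ndim == 0 else out


def signal_sphere_gpd(
    m: Measurement, radius: float, d_ic: float, ctx: SphereContext | None = None
):
    """Sphere GPD attenuation for one measurement (1 exactly at b = 0)."""
    roots = (ctx or default_sphere_context()).bessel_roots
    if m.b == 0:
        return 1.0
    return float(
        sphere_gpd_attenuation(m.b_internal, m.delta, m.Delta, radius, d_ic, roots)
    )
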