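"""PGSE acquisition schemes.

A VERDICT-style protocol is an ordered table of pulsed-gradient spin-echo
(PGSE) measurements, each characterised by the diffusion weighting b, the
gradient pulse duration ``delta`` and separation ``Delta``, the echo time TE
and repetition time TR.  The built-in :func:`innovate_scheme` reproduces the
10-measurement prostate VERDICT protocol used throughout this package: five
nonzero-b shells, each preceded by a b = 0 acquisition at matched (TE, TR).

Unit system (used consistently package-wide)
--------------------------------------------
* times (``delta``, ``Delta``, TE, TR) in **ms**
* lengths (cell radius R) in **μm**, diffusivities in **μm²/ms**
* b-values are *stored* in the clinical unit s/mm² and converted internally
  to ms/μm² (``b / 1000``) so that ``b · D`` is dimensionless
* gradient amplitude G in **T/μm**, with the proton gyromagnetic ratio
  ``GAMMA = 2.6752218744e5 rad ms⁻¹ T⁻¹`` so that
  ``b[ms/μm²] = (γG)² δ² (Δ − δ/3)`` is dimensionally consistent.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GAMMA",
    "Measurement",
    "AcquisitionScheme",
    "innovate_scheme",
    "effective_diffusion_time",
    "gradient_amplitude",
    "read_scheme",
    "write_scheme",
]

#: Proton gyromagnetic ratio, rad ms^-1 T^-1 (2.6752218744e8 rad s^-1 T^-1).
GAMMA = 2.6752218744e5

_COLUMNS = ("b", "delta", "Delta", "te", "tr", "naverages")


class SchemeParseError(ValueError):
    """Raised when a scheme file is malformed or violates an invariant."""


@dataclass(frozen=True)
class Measurement:
    """One PGSE measurement.

    Parameters
    ----------
    b : float
        Diffusion weighting in s/mm² (clinical convention).
    delta, Delta : float
        Gradient pulse duration and separation, ms.
    te, tr : float
        Echo and repetition time, ms.
    naverages : int
        Number of signal averages acquired.
    """

    b: float
    delta: float
    Delta: float
    te: float
    tr: float
    naverages: int = 1

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if not (0 < self.delta <= self.Delta):
            raise ValueError(
                f"need 0 < delta <= Delta, got delta={self.delta}, Delta={self.Delta}"
            )
        if self.te <= 0 or self.tr <= 0:
            raise ValueError("TE and TR must be positive")
        if self.te < self.Delta + self.delta:
            raise ValueError(
                f"TE={self.te} ms too short for Delta+delta={self.Delta + self.delta} ms"
            )
        if self.naverages < 1:
            raise ValueError("naverages must be >= 1")

    @property
    def b_internal(self) -> float:
        """b in ms/μm² (b[s/mm²] / 1000)."""
        return self.b / 1000.0


def effective_diffusion_time(m: Measurement) -> float:
    """Effective diffusion time Δ − δ/3 of a rectangular PGSE pair, ms."""
    return m.Delta - m.delta / 3.0


def gradient_amplitude(m: Measurement) -> float:
    """Gradient amplitude G (T/μm) solving b = γ²G²δ²(Δ − δ/3).

    Raises
    ------
    ValueError
        For b = 0, where the gradient is undefined (callers must treat
        b = 0 rows as carrying no diffusion weighting).
    """
    if m.b == 0:
        raise ValueError("gradient amplitude undefined for b = 0")
    td = effective_diffusion_time(m)
    return math.sqrt(m.b_internal / (m.delta**2 * td)) / GAMMA


@dataclass
class AcquisitionScheme:
    """Ordered list of PGSE measurements."""

    measurements: list[Measurement]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError("scheme must contain at least one measurement")

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AcquisitionScheme)
            and self.measurements == other.measurements
            and self.name == other.name
        )

    # -- array views ------------------------------------------------------
    def _col(self, attr: str) -> np.ndarray:
        return np.array([getattr(m, attr) for m in self.measurements], dtype=float)

    @property
    def b(self) -> np.ndarray:
        """b-values, s/mm²."""
        return self._col("b")

    @property
    def b_internal(self) -> np.ndarray:
        """b-values, ms/μm²."""
        return self.b / 1000.0

    @property
    def delta(self) -> np.ndarray:
        return self._col("delta")

    @property
    def Delta(self) -> np.ndarray:
        return self._col("Delta")

    @property
    def te(self) -> np.ndarray:
        return self._col("te")

    @property
    def tr(self) -> np.ndarray:
        return self._col("tr")

    @property
    def nonzero_mask(self) -> np.ndarray:
        return self.b > 0

    @property
    def nonzero_indices(self) -> np.ndarray:
        return np.flatnonzero(self.nonzero_mask)

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.nonzero_mask)

    def b0_pair_index(self) -> np.ndarray:
        """For each nonzero-b row, the index of its paired b = 0 row.

        The pair is the nearest *preceding* b = 0 row with identical
        (TE, TR).  Raises if any shell has no such partner.
        """
        pairs = []
        for i in self.nonzero_indices:
            m = self.measurements[i]
            found = -1
            for j in range(i - 1, -1, -1):
                mj = self.measurements[j]
                if mj.b == 0 and mj.te == m.te and mj.tr == m.tr:
                    found = j
                    break
            if found < 0:
                raise ValueError(
                    f"measurement {i} (b={m.b}) has no preceding b=0 pair at "
                    f"TE={m.te}, TR={m.tr}"
                )
            pairs.append(found)
        return np.array(pairs, dtype=int)

    def validate_rverdict_pairing(self) -> None:
        """Check every shell has a matched-(TE, TR) b = 0 partner."""
        self.b0_pair_index()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "b": self.b,
                "delta": self.delta,
                "Delta": self.Delta,
                "te": self.te,
                "tr": self.tr,
                "naverages": [m.naverages for m in self.measurements],
            }
        )


#: The five (b; delta; Delta; TE; TR) shells of the prostate VERDICT protocol.
_INNOVATE_SHELLS = (
    (90.0, 3.9, 23.8, 50.0, 2482.0),
    (500.0, 11.4, 31.3, 65.0, 2482.0),
    (1500.0, 23.9, 43.8, 90.0, 2482.0),
    (2000.0, 14.4, 34.4, 71.0, 3945.0),
    (3000.0, 18.9, 38.8, 80.0, 3349.0),
)


def innovate_scheme() -> AcquisitionScheme:
    """The 10-measurement prostate VERDICT protocol.

    Five PGSE shells, each preceded by a b = 0 acquisition at the same
    (TE, TR) (and, by convention, the same nominal delta/Delta).  Averages:
    4 for b < 100 s/mm², 6 otherwise.
    """
    rows: list[Measurement] = []
    for b, delta, Delta, te, tr in _INNOVATE_SHELLS:
        nav = 4 if b < 100 else 6
        rows.append(Measurement(0.0, delta, Delta, te, tr, naverages=4))
        rows.append(Measurement(b, delta, Delta, te, tr, naverages=nav))
    return AcquisitionScheme(rows, name="innovate-verdict")


def write_scheme(scheme: AcquisitionScheme, path) -> None:
    """Write a scheme as a whitespace-delimited table with header.

    Floats are written with ``repr`` precision so write→read round-trips
    bit-exactly.
    """
    with open(path, "w") as fh:
        if scheme.name:
            fh.write(f"# scheme: {scheme.name}\n")
        fh.write(" ".join(_COLUMNS) + "\n")
        for m in scheme.measurements:
            fh.write(
                f"{m.b!r} {m.delta!r} {m.Delta!r} {m.te!r} {m.tr!r} {m.naverages}\n"
            )


def read_scheme(path) -> AcquisitionScheme:
    """Read a whitespace- or comma-delimited scheme table.

    The header must name ``b delta Delta te tr`` (``naverages`` optional).
    Parse failures and invariant violations raise :class:`SchemeParseError`
    naming the offending row and column.
    """
    name = ""
    lines = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("#"):
                if line.startswith("# scheme:"):
                    name = line.split(":", 1)[1].strip()
                continue
            if line:
                lines.append(line)
    if not lines:
        raise SchemeParseError(f"{path}: empty scheme file")
    if "," not in lines[0]:
        lines = [",".join(line.split()) for line in lines]
    try:
        df = pd.read_csv(
            io.StringIO("\n".join(lines)),
            sep=",",
            float_precision="round_trip",  # bit-exact write -> read
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemeParseError(f"{path}: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    for col in _COLUMNS[:5]:
        if col not in df.columns:
            raise SchemeParseError(f"{path}: missing column '{col}'")
    if "naverages" not in df.columns:
        df["naverages"] = 1
    rows: list[Measurement] = []
    for i, rec in df.iterrows():
        for col in _COLUMNS:
            try:
                float(rec[col])
            except (TypeError, ValueError):
                raise SchemeParseError(
                    f"{path}: row {i}, column '{col}': non-numeric value {rec[col]!r}"
                ) from None
        try:
            rows.append(
                Measurement(
                    b=float(rec["b"]),
                    delta=float(rec["delta"]),
                    Delta=float(rec["Delta"]),
                    te=float(rec["te"]),
                    tr=float(rec["tr"]),
                    naverages=int(rec["naverages"]),
                )
            )
        except ValueError as exc:
            raise SchemeParseError(f"{path}: row {i}: {exc}") from exc
    return AcquisitionScheme(rows, name=name)
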