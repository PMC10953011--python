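"""Spectrophotometric assay processing.

Converts raw measurements into the quantities the kinetic model consumes:

* initial rates from absorbance-vs-time traces (nitrofurazone reduction is
  followed at 420 nm with a molar absorbance change of 4300 M^-1 cm^-1);
* enzyme concentration from A280 corrected for free-FMN absorbance at 454 nm;
* ionic strength of the assay buffer (the dicarboxylate inhibitors are added
  at constant total ionic strength, treating fumarate as a dianion at pH 7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbsorbanceTrace",
    "ExtinctionSet",
    "BufferComponent",
    "NFSA_EXTINCTIONS",
    "NFSB_EXTINCTIONS",
    "DELTA_EPSILON_420",
    "initial_rate_from_trace",
    "protein_concentration",
    "ionic_strength",
    "read_trace_csv",
    "write_trace_csv",
]

#: Molar absorbance change of the nitrofurazone/NAD(P)H reaction at 420 nm,
#: M^-1 cm^-1.
DELTA_EPSILON_420 = 4300.0


@dataclass(frozen=True)
class AbsorbanceTrace:
    """Timed absorbance readings at a single wavelength.

    ``delta_epsilon`` (M^-1 cm^-1) and ``path_length`` (cm) carry the
    constants needed to convert an absorbance slope into a molar rate.
    """

    times: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: float = 420.0
    path_length: float = 1.0
    delta_epsilon: float = DELTA_EPSILON_420

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        absorbance = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "absorbance", absorbance)
        if times.ndim != 1 or absorbance.shape != times.shape:
            raise ValueError("times and absorbance must be 1-D arrays of equal length")
        if times.size < 3:
            raise ValueError("a trace needs at least 3 samples")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(absorbance)):
            raise ValueError("absorbance values must be finite")
        if self.path_length <= 0:
            raise ValueError("path length must be > 0")
        if self.delta_epsilon <= 0:
            raise ValueError("delta_epsilon must be > 0")


@dataclass(frozen=True)
class ExtinctionSet:
    """Molar absorbances (M^-1 cm^-1) for flavoprotein concentration estimates."""

    eps_fmn_454: float
    eps_fmn_280: float
    eps_protein_280: float

    def __post_init__(self) -> None:
        for name in ("eps_fmn_454", "eps_fmn_280", "eps_protein_280"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


#: Extinction coefficients for NfsA: FMN 12200 (454 nm), FMN 20970 (280 nm),
#: apoprotein 31190 (280 nm, from amino-acid composition).
NFSA_EXTINCTIONS = ExtinctionSet(12_200.0, 20_970.0, 31_190.0)
#: NfsB uses the same FMN values with an apoprotein absorbance of 22460.
NFSB_EXTINCTIONS = ExtinctionSet(12_200.0, 20_970.0, 22_460.0)


@dataclass(frozen=True)
class BufferComponent:
    """One dissolved species contributing ions to the buffer.

    ``ions`` lists ``(charge, count)`` pairs per formula unit; e.g. the
    disodium salt of fumarate is ``((-2, 1), (+1, 2))``.
    """

    name: str
    concentration_mm: float
    ions: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.concentration_mm < 0:
            raise ValueError("concentration must be >= 0")
        for charge, count in self.ions:
            if count <= 0:
                raise ValueError("ion stoichiometry must be positive")


def initial_rate_from_trace(
    trace: AbsorbanceTrace,
    window: tuple[float, float] = (0.0, 60.0),
) -> float:
    """Initial rate (M s^-1) from the linear slope of an absorbance trace.

    Fits an unweighted ordinary-least-squares line to absorbance vs time over
    ``window`` (seconds) and divides the slope magnitude by
    ``delta_epsilon * path_length``.  The magnitude convention means the same
    value is returned whether the chromophore is consumed or produced.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed window start")
    mask = (trace.times >= start) & (trace.times <= end)
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 trace points inside window {window}")
    t = trace.times[mask]
    y = trace.absorbance[mask]
    if np.ptp(t) == 0:
        raise ValueError("zero time variance inside window")
    slope = np.polyfit(t, y, 1)[0]
    return abs(slope) / (trace.delta_epsilon * trace.path_length)


def protein_concentration(a280: float, a454: float, ext: ExtinctionSet) -> float:
    """Flavoprotein concentration (M) from A280 with a free-FMN correction.

    Both the apoprotein and the FMN cofactor absorb at 280 nm while only FMN
    absorbs at 454 nm, so the FMN contribution at 280 nm is estimated as
    ``(A454 / eps_fmn_454) * eps_fmn_280`` and subtracted before dividing by
    the protein extinction coefficient.  A correction exceeding A280 clamps
    the result at zero with a warning.
    """
    if a280 < 0 or a454 < 0:
        raise ValueError("absorbances must be >= 0")
    corrected = a280 - (a454 / ext.eps_fmn_454) * ext.eps_fmn_280
    if corrected < 0:
        warnings.warn(
            "FMN correction exceeds A280; clamping protein concentration at 0",
            stacklevel=2,
        )
        corrected = 0.0
    return corrected / ext.eps_protein_280


def ionic_strength(components: Iterable[BufferComponent]) -> float:
    """Total ionic strength I = 0.5 * sum(c_i * z_i^2) over all ions, in mM."""
    total = 0.0
    for comp in components:
        for charge, count in comp.ions:
            total += comp.concentration_mm * count * charge**2
    return 0.5 * total


def read_trace_csv(path: str | Path, **trace_kwargs) -> AbsorbanceTrace:
    """Read a two-column trace CSV (``time_s``, ``absorbance``; header required)."""
    df = pd.read_csv(path)
    missing = {"time_s", "absorbance"} - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} missing columns: {sorted(missing)}")
    return AbsorbanceTrace(df["time_s"].to_numpy(), df["absorbance"].to_numpy(), **trace_kwargs)


def write_trace_csv(trace: AbsorbanceTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times, "absorbance": trace.absorbance}).to_csv(
        path, index=False
    )
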