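"""Steady-state rate laws for the substituted-enzyme (ping-pong bi-bi) mechanism.

The central rate equation describes a two-substrate reaction in which the
first substrate (A, here nitrofurazone) reduces the enzyme-bound flavin and
leaves before the second substrate (B, the nicotinamide cofactor NADPH or
NADH) binds.  A dead-end inhibitor I may compete with either half-reaction,
with a separate inhibition constant for each half::

    v/E = kcat * A * B / ( Km_A * B * (1 + I/Ki_A)
                         + Km_B * A * (1 + I/Ki_B)
                         + A * B )

All concentrations are in micromolar and rates are normalised per enzyme
(v/E, in s^-1).  An absent Ki denotes "no inhibition of this half": its
(1 + I/Ki) factor is identically 1, equivalent to Ki -> infinity, and the
corresponding model variant simply has one parameter fewer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "KineticParameters",
    "ConcentrationPoint",
    "rate_ping_pong",
    "rate_no_inhibition",
    "rate_grid",
    "apparent_parameters",
]


@dataclass(frozen=True)
class KineticParameters:
    """Mechanistic parameter set of the ping-pong rate law.

    Parameters
    ----------
    kcat : float
        Turnover number, s^-1.
    km_a : float
        Michaelis constant for substrate A (the nitroaromatic electron
        acceptor, e.g. nitrofurazone), uM.
    km_b : float
        Michaelis constant for substrate B (NAD(P)H), uM.
    ki_a : float or None
        Dead-end inhibition constant on the A half-reaction (the term
        containing ``km_a``), uM.  ``None`` means that half is not inhibited.
    ki_b : float or None
        Inhibition constant on the B half-reaction, uM, or ``None``.
    """

    kcat: float
    km_a: float
    km_b: float
    ki_a: float | None = None
    ki_b: float | None = None

    def __post_init__(self) -> None:
        for name in ("kcat", "km_a", "km_b"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        for name in ("ki_a", "ki_b"):
            value = getattr(self, name)
            if value is not None and (not np.isfinite(value) or value <= 0):
                raise ValueError(f"{name} must be finite and > 0 or None, got {value!r}")

    def without_inhibition(self) -> "KineticParameters":
        """Return a copy with both inhibition constants absent."""
        return KineticParameters(self.kcat, self.km_a, self.km_b)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "kcat": self.kcat,
            "km_a": self.km_a,
            "km_b": self.km_b,
            "ki_a": self.ki_a,
            "ki_b": self.ki_b,
        }


@dataclass(frozen=True)
class ConcentrationPoint:
    """One assay condition: substrate, inhibitor and enzyme concentrations (uM).

    ``e`` is optional because the rate law is written per enzyme; it is only
    needed to convert v/E into an absolute rate (typical assays use ~0.01 uM
    enzyme).
    """

    a: float
    b: float
    i: float = 0.0
    e: float | None = None

    def __post_init__(self) -> None:
        for name in ("a", "b", "i"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"concentration {name} must be finite and >= 0, got {value!r}")
        if self.e is not None and (not np.isfinite(self.e) or self.e < 0):
            raise ValueError(f"enzyme concentration must be finite and >= 0, got {self.e!r}")


def rate_grid(
    params: KineticParameters,
    a: np.ndarray | float,
    b: np.ndarray | float,
    i: np.ndarray | float = 0.0,
) -> np.ndarray | float:
    """Vectorised ping-pong rate v/E (s^-1) over arrays of concentrations.

    Broadcasts ``a``, ``b`` and ``i`` together.  Points with A = 0 or B = 0
    return 0 (no turnover without either substrate), including the fully
    degenerate A = B = 0 corner.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    i = np.asarray(i, dtype=float)
    if np.any(a < 0) or np.any(b < 0) or np.any(i < 0):
        raise ValueError("concentrations must be >= 0")

    fac_a = 1.0 + i / params.ki_a if params.ki_a is not None else np.ones_like(i)
    fac_b = 1.0 + i / params.ki_b if params.ki_b is not None else np.ones_like(i)
    numer = params.kcat * a * b
    denom = params.km_a * b * fac_a + params.km_b * a * fac_b + a * b
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(numer > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    if v.ndim == 0:
        return float(v)
    return v


def rate_ping_pong(params: KineticParameters, point: ConcentrationPoint) -> float:
    """Normalised steady-state rate v/E (s^-1) at one concentration point."""
    return float(rate_grid(params, point.a, point.b, point.i))


def rate_no_inhibition(params: KineticParameters, point: ConcentrationPoint) -> float:
    """Ping-pong rate ignoring any inhibition terms (both Ki treated absent).

    Equals :func:`rate_ping_pong` evaluated at I = 0 exactly.
    """
    return float(rate_grid(params.without_inhibition(), point.a, point.b, 0.0))


def apparent_parameters(
    params: KineticParameters,
    fixed_substrate: Literal["A", "B"],
    fixed_conc: float,
    i: float = 0.0,
) -> tuple[float, float]:
    """Reduce the two-substrate law to a one-substrate Michaelis-Menten form.

    Holding one substrate at ``fixed_conc`` (uM) and the inhibitor at ``i``,
    the ping-pong equation in the remaining substrate S is exactly
    ``Vmax_app * S / (Km_app + S)``.  With substrate B fixed::

        Vmax_app = kcat / (1 + Km_B * (1 + I/Ki_B) / B)
        Km_app   = Km_A * (1 + I/Ki_A) / (1 + Km_B * (1 + I/Ki_B) / B)

    and symmetrically with A fixed.  Returns ``(vmax_app, km_app)`` in
    (s^-1, uM).
    """
    if fixed_conc <= 0 or not np.isfinite(fixed_conc):
        raise ValueError("fixed co-substrate concentration must be > 0 for the apparent form")
    if i < 0:
        raise ValueError("inhibitor concentration must be >= 0")
    fac_a = 1.0 + i / params.ki_a if params.ki_a is not None else 1.0
    fac_b = 1.0 + i / params.ki_b if params.ki_b is not None else 1.0
    if fixed_substrate == "B":
        shared = 1.0 + params.km_b * fac_b / fixed_conc
        return params.kcat / shared, params.km_a * fac_a / shared
    if fixed_substrate == "A":
        shared = 1.0 + params.km_a * fac_a / fixed_conc
        return params.kcat / shared, params.km_b * fac_b / shared
    raise ValueError(f"fixed_substrate must be 'A' or 'B', got {fixed_substrate!r}")
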