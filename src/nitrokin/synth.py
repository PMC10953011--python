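"""Synthetic assay data with the statistical structure of real nitroreductase
steady-state experiments.

The canonical design measures two "arms" — one substrate varied over a
dilution series at a fixed concentration of the other, and vice versa — each
arm repeated over a series of inhibitor concentrations that always includes
an inhibitor-free control.  Measurement error on an initial rate is modelled
as multiplicative Gaussian noise (spectrophotometric slope error scales with
the signal), truncated so rates stay non-negative.

Built-in presets reproduce the published study conditions:

* ``fumarate_nfsa`` — NfsA with fumarate: nitrofurazone varied at 100 uM
  NADPH, NADPH varied at 75 uM nitrofurazone, fumarate up to 2 mM.
* ``succinate_nfsa`` — NfsA with succinate: nitrofurazone varied at 100 uM
  NADPH, NADPH varied at 30 uM nitrofurazone, succinate up to 30 mM.
* ``nfsb`` — NfsB with NADH: nitrofurazone varied at 100 uM NADH, NADH
  varied at 300 uM nitrofurazone, putative inhibitor at 0 and 1 mM.

Substrate grids are 7-point two-fold dilution series spanning roughly
0.15x-10x the corresponding Michaelis constant; the published figures show
but do not tabulate their exact grids, so these are package defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .assay import AbsorbanceTrace, DELTA_EPSILON_420
from .datasets import RATE_COLUMNS, RateDataset
from .rate_laws import ConcentrationPoint, KineticParameters, rate_grid

__all__ = [
    "DesignConfig",
    "REFERENCE_PARAMETERS",
    "default_designs",
    "simulate_rates",
    "simulate_trace",
]

#: Published global parameter estimates used as generating truths for the
#: presets (kcat s^-1; Km, Ki uM).  The NfsB entry combines the per-arm
#: apparent constants reported for that enzyme into one uninhibited
#: parameter set.
REFERENCE_PARAMETERS: dict[str, KineticParameters] = {
    "fumarate_nfsa": KineticParameters(kcat=25.0, km_a=27.0, km_b=29.0, ki_a=960.0, ki_b=145.0),
    "succinate_nfsa": KineticParameters(kcat=51.0, km_a=58.0, km_b=69.0, ki_a=None, ki_b=4300.0),
    "nfsb": KineticParameters(kcat=36.0, km_a=20.0, km_b=32.0),
}


def _twofold_series(top: float, n: int = 7) -> tuple[float, ...]:
    return tuple(float(top / 2**k) for k in reversed(range(n)))


@dataclass(frozen=True)
class DesignConfig:
    """Concentration design and noise model for one simulated experiment.

    Concentrations in uM.  ``a_grid`` is the substrate-A (nitrofurazone)
    series measured at ``fixed_b`` uM of substrate B; ``b_grid`` is the
    B series at ``fixed_a``.  ``noise_cv`` is the coefficient of variation
    of multiplicative noise; ``noise_sd`` an additive alternative (s^-1).
    """

    a_grid: tuple[float, ...]
    b_grid: tuple[float, ...]
    fixed_a: float
    fixed_b: float
    inhibitor_levels: tuple[float, ...] = (0.0,)
    replicates: int = 3
    noise_model: Literal["multiplicative", "additive"] = "multiplicative"
    noise_cv: float = 0.05
    noise_sd: float = 0.0
    enzyme_um: float = 0.01
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.a_grid or not self.b_grid:
            raise ValueError("substrate grids must be non-empty")
        if min(self.a_grid) < 0 or min(self.b_grid) < 0:
            raise ValueError("substrate grids must be non-negative")
        if self.fixed_a < 0 or self.fixed_b < 0:
            raise ValueError("fixed concentrations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0 or self.noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if 0.0 not in self.inhibitor_levels:
            raise ValueError("designs must include an inhibitor-free control (level 0)")

    def as_dict(self) -> dict:
        return asdict(self)


def default_designs(
    replicates: int = 3, noise_cv: float = 0.05, seed: int = 0
) -> dict[str, DesignConfig]:
    """Named presets mirroring the published experimental designs."""
    return {
        "fumarate_nfsa": DesignConfig(
            a_grid=_twofold_series(270.0),
            b_grid=_twofold_series(290.0),
            fixed_a=75.0,
            fixed_b=100.0,
            inhibitor_levels=(0.0, 200.0, 500.0, 1000.0, 2000.0),
            replicates=replicates,
            noise_cv=noise_cv,
            seed=seed,
            name="fumarate_nfsa",
        ),
        "succinate_nfsa": DesignConfig(
            a_grid=_twofold_series(580.0),
            b_grid=_twofold_series(690.0),
            fixed_a=30.0,
            fixed_b=100.0,
            inhibitor_levels=(0.0, 5_000.0, 10_000.0, 20_000.0, 30_000.0),
            replicates=replicates,
            noise_cv=noise_cv,
            seed=seed,
            name="succinate_nfsa",
        ),
        "nfsb": DesignConfig(
            a_grid=_twofold_series(200.0),
            b_grid=_twofold_series(320.0),
            fixed_a=300.0,
            fixed_b=100.0,
            inhibitor_levels=(0.0, 1000.0),
            replicates=replicates,
            noise_cv=noise_cv,
            seed=seed,
            name="nfsb",
        ),
    }


def simulate_rates(params: KineticParameters, design: DesignConfig) -> RateDataset:
    """Draw a noisy initial-rate dataset from the ping-pong rate law.

    Each replicate of each (arm, inhibitor level, substrate concentration)
    cell is the exact model rate perturbed by the design's noise model and
    clipped at zero.  Reproducible: the same config gives the same dataset.
    """
    rows_a, rows_b, rows_i = [], [], []
    for level in design.inhibitor_levels:
        for a in design.a_grid:
            rows_a.append(a)
            rows_b.append(design.fixed_b)
            rows_i.append(level)
        for b in design.b_grid:
            rows_a.append(design.fixed_a)
            rows_b.append(b)
            rows_i.append(level)
    a = np.repeat(np.asarray(rows_a, dtype=float), design.replicates)
    b = np.repeat(np.asarray(rows_b, dtype=float), design.replicates)
    i = np.repeat(np.asarray(rows_i, dtype=float), design.replicates)
    replicate = np.tile(np.arange(1, design.replicates + 1), len(rows_a))

    v_true = np.asarray(rate_grid(params, a, b, i), dtype=float)
    rng = np.random.default_rng(design.seed)
    eps = rng.standard_normal(v_true.shape)
    if design.noise_model == "multiplicative":
        v = v_true * (1.0 + design.noise_cv * eps)
    else:
        v = v_true + design.noise_sd * eps
    v = np.clip(v, 0.0, None)

    data = pd.DataFrame(
        {
            "A_uM": a,
            "B_uM": b,
            "I_uM": i,
            "E_uM": np.full_like(a, design.enzyme_um),
            "v_over_E_per_s": v,
            "replicate": replicate,
        },
        columns=RATE_COLUMNS,
    )
    metadata = {
        "generator": "nitrokin.synth.simulate_rates",
        "version": __version__,
        "params": params.as_dict(),
        "design": design.as_dict(),
        "seed": design.seed,
    }
    return RateDataset(data, metadata)


def simulate_trace(
    params: KineticParameters,
    point: ConcentrationPoint,
    duration_s: float = 120.0,
    interval_s: float = 1.0,
    noise_sd_au: float = 0.0,
    depletion: bool = False,
    depletion_step_s: float = 0.01,
    a0_au: float = 1.0,
    path_length: float = 1.0,
    delta_epsilon: float = DELTA_EPSILON_420,
    seed: int = 0,
) -> AbsorbanceTrace:
    """Simulate an A420 progress curve for one assay condition.

    The chromophore (nitrofurazone) is consumed, so absorbance falls from
    ``a0_au`` at ``v * delta_epsilon * path_length`` AU/s, where v (M/s) is
    the model rate times the enzyme concentration of ``point``.  In
    ``depletion`` mode d[A]/dt = -v is integrated by fixed Euler steps so
    the curve flattens as substrate runs out; otherwise the trace is an
    exact line.  Optional additive Gaussian read noise.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if interval_s <= 0 or interval_s > duration_s:
        raise ValueError("sampling interval must be in (0, duration]")
    if depletion_step_s <= 0 or depletion_step_s > duration_s:
        raise ValueError("depletion step must be in (0, duration]")
    e_um = point.e if point.e is not None else 0.0

    times = np.arange(0.0, duration_s + 0.5 * interval_s, interval_s)
    if not depletion:
        v_molar = float(rate_grid(params, point.a, point.b, point.i)) * e_um * 1e-6
        absorbance = a0_au - v_molar * delta_epsilon * path_length * times
    else:
        # Euler integration of substrate-A depletion at fixed co-substrate
        n_steps = int(np.ceil(duration_s / depletion_step_s))
        a_um = point.a
        consumed_um = 0.0
        t_grid = [0.0]
        consumed = [0.0]
        for k in range(n_steps):
            v_um_s = float(rate_grid(params, a_um, point.b, point.i)) * e_um
            step = min(depletion_step_s, duration_s - k * depletion_step_s)
            a_um = max(a_um - v_um_s * step, 0.0)
            consumed_um += v_um_s * step
            t_grid.append(min((k + 1) * depletion_step_s, duration_s))
            consumed.append(consumed_um)
        consumed_at_times = np.interp(times, t_grid, consumed)
        absorbance = a0_au - consumed_at_times * 1e-6 * delta_epsilon * path_length

    if noise_sd_au > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + noise_sd_au * rng.standard_normal(times.shape)

    return AbsorbanceTrace(
        times=times,
        absorbance=absorbance,
        path_length=path_length,
        delta_epsilon=delta_epsilon,
    )
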