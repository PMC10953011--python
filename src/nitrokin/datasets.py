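"""Initial-rate datasets and their on-disk CSV representation.

The shared rate-table format has columns ``A_uM`` (nitrofurazone), ``B_uM``
(NAD(P)H), ``I_uM`` (inhibitor), ``E_uM`` (enzyme), ``v_over_E_per_s``
(normalised rate) and ``replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["RATE_COLUMNS", "RateDataset", "read_rate_csv", "write_rate_csv"]

RATE_COLUMNS = ["A_uM", "B_uM", "I_uM", "E_uM", "v_over_E_per_s", "replicate"]


@dataclass
class RateDataset:
    """Initial-rate observations over a concentration design.

    ``data`` holds one row per observation with the :data:`RATE_COLUMNS`
    schema.  ``metadata`` records assay context (buffer, ionic strength in mM,
    temperature, DMSO fraction, enzyme/inhibitor names) and, for simulated
    data, full generator provenance.
    """

    data: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(RATE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"rate table missing columns: {sorted(missing)}")
        if len(self.data) < 1:
            raise ValueError("a rate dataset needs at least one observation")
        v = self.data["v_over_E_per_s"].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("all rates must be finite and >= 0")
        for col in ("A_uM", "B_uM", "I_uM"):
            c = self.data[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(c)) or np.any(c < 0):
                raise ValueError(f"column {col} must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def a(self) -> np.ndarray:
        return self.data["A_uM"].to_numpy(dtype=float)

    @property
    def b(self) -> np.ndarray:
        return self.data["B_uM"].to_numpy(dtype=float)

    @property
    def i(self) -> np.ndarray:
        return self.data["I_uM"].to_numpy(dtype=float)

    @property
    def v(self) -> np.ndarray:
        return self.data["v_over_E_per_s"].to_numpy(dtype=float)

    def inhibitor_levels(self) -> np.ndarray:
        return np.unique(self.i)

    def subset(self, mask: np.ndarray) -> "RateDataset":
        return RateDataset(self.data.loc[mask].reset_index(drop=True), dict(self.metadata))


def read_rate_csv(path: str | Path, metadata: dict[str, Any] | None = None) -> RateDataset:
    """Load a rate-table CSV into a :class:`RateDataset`."""
    return RateDataset(pd.read_csv(path), metadata or {})


def write_rate_csv(dataset: RateDataset, path: str | Path) -> None:
    dataset.data.to_csv(path, index=False)
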