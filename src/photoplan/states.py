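"""Three-state cell-fate classification from death-rate values.

A death-rate value d in [0, 1] is mapped to one of three clinically
motivated states by two thresholds 0 < H_TH < D_TH < 1:

    dead        d > D_TH
    affected    H_TH <= d <= D_TH   (partially damaged, still live)
    unaffected  d < H_TH

The boundary convention is fixed and documented: "dead" is open at D_TH and
"affected" is the closed interval, so every d receives exactly one label.
Defaults D_TH = 0.6 and H_TH = 0.3 place the unaffected band at death rates
comparable to untreated controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

STATES = ("dead", "affected", "unaffected")


@dataclass(frozen=True)
class StateThresholds:
    """Death-rate thresholds (d_th = D_TH, h_th = H_TH), 0 < h_th < d_th < 1."""

    d_th: float = 0.6
    h_th: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.h_th < self.d_th < 1.0):
            raise ValueError(
                f"thresholds must satisfy 0 < h_th < d_th < 1, got h_th={self.h_th}, d_th={self.d_th}"
            )


@dataclass(frozen=True)
class StateProbabilities:
    """Population probabilities of the three states; must sum to 1."""

    p_d: float
    p_a: float
    p_na: float

    def __post_init__(self) -> None:
        for name, v in (("p_d", self.p_d), ("p_a", self.p_a), ("p_na", self.p_na)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.p_d + self.p_a + self.p_na - 1.0) > 1e-9:
            raise ValueError("state probabilities must sum to 1 within 1e-9")


def classify_rate(d: float, thresholds: StateThresholds = StateThresholds()) -> str:
    """Label a single death-rate value as dead / affected / unaffected."""
    d = float(d)
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"death rate must be in [0, 1], got {d}")
    if d > thresholds.d_th:
        return "dead"
    if d >= thresholds.h_th:
        return "affected"
    return "unaffected"


def classify_population(
    rates: Sequence[float], thresholds: StateThresholds = StateThresholds()
) -> StateProbabilities:
    """Empirical state probabilities of a population of per-cell death rates."""
    arr = np.asarray(rates, dtype=float)
    if arr.size == 0:
        raise ValueError("rates must be non-empty")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("all rates must be in [0, 1]")
    n = arr.size
    n_dead = int(np.sum(arr > thresholds.d_th))
    n_unaffected = int(np.sum(arr < thresholds.h_th))
    n_affected = n - n_dead - n_unaffected
    return StateProbabilities(p_d=n_dead / n, p_a=n_affected / n, p_na=n_unaffected / n)


def state_map_from_surface(
    surface,
    tau_grid: Sequence[float],
    intensity_grid: Sequence[float],
    thresholds: StateThresholds = StateThresholds(),
) -> pd.DataFrame:
    """Predicted state label over a (tau, intensity) lattice.

    Returns a tidy frame with columns ``tau``, ``intensity``,
    ``death_fraction`` and ``state``, one row per lattice cell, suitable for
    plotting treatment-planning maps of the dead / affected / unaffected
    regions.
    """
    taus = np.asarray(tau_grid, dtype=float)
    i0s = np.asarray(intensity_grid, dtype=float)
    tt, ii = np.meshgrid(taus, i0s, indexing="ij")
    d = np.asarray(surface.predict(tt.ravel(), ii.ravel()))
    labels = [classify_rate(v, thresholds) for v in d]
    return pd.DataFrame(
        {
            "tau": tt.ravel(),
            "intensity": ii.ravel(),
            "death_fraction": d,
            "state": labels,
        }
    )
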