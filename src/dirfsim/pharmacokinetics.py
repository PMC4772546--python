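"""Drug concentration dynamics under a dosing schedule.

Each administered drug follows one-compartment kinetics with first-order
elimination and stochastic fluctuation,

    dD = (-k_e * D + v(t)) dt + sigma_D * D * dW,

where ``v(t)`` is the delivery rate implied by the repeating on/off pattern
of a :class:`~dirfsim.config.DosingSchedule` and ``k_e`` is the patient's
metabolic rate.  The noise is multiplicative so that concentrations remain
non-negative in distribution; the Euler–Maruyama discretization additionally
truncates at zero.  One independent Wiener process drives each drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DosingSchedule

__all__ = ["DrugPath", "delivery_rate", "pk_step", "simulate_drug_path"]


@dataclass(frozen=True)
class DrugPath:
    """A simulated concentration path for one drug on a fixed time grid."""

    drug: str
    t: np.ndarray
    concentration: np.ndarray
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: columns ``time``, ``drug``, ``concentration``."""
        return pd.DataFrame({
            "time": self.t,
            "drug": self.drug,
            "concentration": self.concentration,
        })


def delivery_rate(t: float, schedule: DosingSchedule) -> float:
    """Delivery rate ``v(t)`` of the repeating on/off pattern at time ``t`` (days).

    Returns ``schedule.dose`` during "on" days of each cycle and 0 during
    "off" days or past the schedule horizon.  Pure function of its arguments.
    """
    if t < 0:
        raise ValueError(f"delivery_rate: t must be >= 0, got {t}")
    if t >= schedule.horizon or schedule.dose == 0:
        return 0.0
    period = schedule.days_on + schedule.days_off
    phase = math.fmod(t, period)
    return float(schedule.dose) if phase < schedule.days_on else 0.0


def pk_step(D: float, v: float, k_e: float, sigma_D: float,
            h: float, z: float) -> float:
    """One Euler–Maruyama update of the PK equation, truncated at zero."""
    D_next = D + (-k_e * D + v) * h + sigma_D * D * math.sqrt(h) * z
    return D_next if D_next > 0.0 else 0.0


def simulate_drug_path(schedule: DosingSchedule, k_e: float, sigma_D: float,
                       grid: np.ndarray, seed: int | None = None,
                       d0: float = 0.0) -> DrugPath:
    """Simulate ``D(t)`` on ``grid`` by the Euler–Maruyama scheme.

    Parameters
    ----------
    schedule:
        Dosing pattern supplying the delivery rate ``v(t)``.
    k_e, sigma_D:
        Elimination rate (1/day) and multiplicative noise amplitude.
    grid:
        Strictly increasing array of times (days) starting at ``t >= 0``;
        the same grid the cellular simulation uses.
    seed:
        Seed for the Wiener increments.  With ``sigma_D = 0`` the path is
        deterministic and independent of the seed.
    d0:
        Initial concentration ``D(grid[0])``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    if grid[0] < 0:
        raise ValueError("grid must start at t >= 0")
    for name, val in (("k_e", k_e), ("sigma_D", sigma_D), ("d0", d0)):
        if not math.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val}")
    if k_e < 0 or sigma_D < 0 or d0 < 0:
        raise ValueError("k_e, sigma_D and d0 must be >= 0")

    rng = np.random.default_rng(seed)
    z = rng.standard_normal(grid.size - 1) if sigma_D > 0 else np.zeros(grid.size - 1)
    path = np.empty_like(grid)
    path[0] = d0
    D = float(d0)
    for k in range(grid.size - 1):
        h = grid[k + 1] - grid[k]
        D = pk_step(D, delivery_rate(float(grid[k]), schedule),
                    k_e, sigma_D, float(h), float(z[k]))
        path[k + 1] = D
    return DrugPath(drug=schedule.drug, t=grid, concentration=path, seed=seed)
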