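"""Virtual cohorts, progression-free survival and population summaries.

A cohort is ``n_patients`` independent realizations of the single-patient
jump-diffusion model, with patient ``i`` seeded deterministically from
``(base_seed, i)`` so that treatment arms sharing a base seed use common
random numbers.  Progression-free survival (PFS) is the first trajectory
node at which the total tumor burden ``C_S + C_R + C_M`` exceeds the
progression threshold; patients that never cross are administratively
censored at the horizon.  No interpolation is used for crossing detection:
the jump-adapted mesh makes threshold crossings sharp at jump nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortConfig, DosingSchedule, ModelParameters, patient_seed
from .dynamics import PatientTrajectory, simulate_patient

__all__ = [
    "CohortResult",
    "pfs_time",
    "simulate_cohort",
    "survival_curve",
    "survival_frequencies",
    "metastatic_fraction",
    "burden_distribution",
    "metabolism_experiment",
]


@dataclass
class CohortResult:
    """Summary of one simulated cohort.

    ``burden`` holds the total tumor burden of every patient on the shared
    regular grid ``grid`` (patients x time points), which is what the
    survival, histogram and sensitivity computations consume; full
    trajectories are not retained.
    """

    pfs_days: np.ndarray            # per-patient PFS time (days)
    censored: np.ndarray            # True where no crossing before horizon
    end_state: pd.DataFrame         # C_S, C_R, C_M, C_K at horizon per patient
    seeds: list[tuple[int, int]]    # (base_seed, patient index)
    grid: np.ndarray                # shared regular time grid
    burden: np.ndarray              # total burden, shape (n_patients, len(grid))
    C_M_grid: np.ndarray            # metastatic burden on the same grid
    params: ModelParameters
    cohort_cfg: CohortConfig
    schedules: list[DosingSchedule]

    @property
    def n(self) -> int:
        return len(self.pfs_days)

    def median_pfs(self) -> float:
        """Median PFS in days (censored times enter at the horizon)."""
        return float(np.median(self.pfs_days))

    def patients_frame(self) -> pd.DataFrame:
        df = self.end_state.copy()
        df.insert(0, "patient", np.arange(self.n))
        df.insert(1, "pfs_days", self.pfs_days)
        df.insert(2, "censored", self.censored)
        df["total_end"] = df["C_S"] + df["C_R"] + df["C_M"]
        return df


def pfs_time(traj: PatientTrajectory, theta_prog: float = 1.6
             ) -> tuple[float, bool]:
    """Progression-free survival of one trajectory.

    Returns ``(time, censored)``: the first node (regular or jump) at which
    ``C_S + C_R + C_M`` exceeds ``theta_prog``, or the final time with
    ``censored=True`` if the burden never crosses the threshold.
    """
    total = traj.total()
    above = np.nonzero(total > theta_prog)[0]
    if above.size:
        return float(traj.t[above[0]]), False
    return float(traj.t[-1]), True


def simulate_cohort(p: ModelParameters, schedules: list[DosingSchedule],
                    cohort_cfg: CohortConfig) -> CohortResult:
    """Simulate ``n_patients`` independent patients with derived seeds."""
    n = cohort_cfg.n_patients
    grid: np.ndarray | None = None
    pfs = np.empty(n)
    cens = np.zeros(n, dtype=bool)
    burden_rows = []
    cm_rows = []
    ends = []
    seeds = []
    for i in range(n):
        ss = patient_seed(cohort_cfg.base_seed, i)
        try:
            traj = simulate_patient(p, schedules, cohort_cfg, ss)
        except Exception as exc:
            raise RuntimeError(
                f"patient {i} (base_seed={cohort_cfg.base_seed}) failed: {exc}"
            ) from exc
        reg = traj.regular()
        if grid is None:
            grid = reg.t
        pfs[i], cens[i] = pfs_time(traj, p.theta_prog)
        burden_rows.append(reg.total())
        cm_rows.append(reg.C_M)
        ends.append((reg.C_S[-1], reg.C_R[-1], reg.C_M[-1], reg.C_K[-1]))
        seeds.append((cohort_cfg.base_seed, i))
    end_state = pd.DataFrame(ends, columns=["C_S", "C_R", "C_M", "C_K"])
    return CohortResult(
        pfs_days=pfs, censored=cens, end_state=end_state, seeds=seeds,
        grid=grid, burden=np.vstack(burden_rows), C_M_grid=np.vstack(cm_rows),
        params=p, cohort_cfg=cohort_cfg, schedules=list(schedules),
    )


def survival_curve(cohort: CohortResult, grid: np.ndarray | None = None
                   ) -> pd.DataFrame:
    """Fraction of patients progression-free at each time point.

    ``S(t) = #{PFS > t}/n``; censored patients count as surviving through
    the horizon.  ``S(0) = 1`` because progression cannot occur at therapy
    start (the threshold exceeds the initial burden).
    """
    if grid is None:
        grid = cohort.grid
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < 0 or grid.max() > cohort.cohort_cfg.horizon + 1e-9):
        raise ValueError("survival grid must lie within [0, horizon]")
    pfs = cohort.pfs_days
    cens = cohort.censored
    # censored patients never progress within the study window
    effective = np.where(cens, np.inf, pfs)
    S = (effective[None, :] > grid[:, None]).mean(axis=1)
    return pd.DataFrame({"time": grid, "survival": S})


def survival_frequencies(cohort: CohortResult, bin_edges: np.ndarray
                         ) -> pd.DataFrame:
    """Histogram of observed PFS times; censored patients reported separately."""
    bin_edges = np.asarray(bin_edges, dtype=float)
    if cohort.n == 0:
        raise ValueError("empty cohort")
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    observed = cohort.pfs_days[~cohort.censored]
    counts, _ = np.histogram(observed, bins=bin_edges)
    df = pd.DataFrame({
        "bin_left": bin_edges[:-1],
        "bin_right": bin_edges[1:],
        "count": counts,
    })
    df.attrs["n_censored"] = int(cohort.censored.sum())
    return df


def metastatic_fraction(cohort: CohortResult, theta_met: float | None = None
                        ) -> float:
    """Fraction of patients with metastatic burden above ``theta_met`` at horizon.

    The threshold (default: the parameter set's ``theta_met = 1``) separates
    the two modes of the all-or-none metastatic onset.
    """
    if theta_met is None:
        theta_met = cohort.params.theta_met
    return float((cohort.end_state["C_M"].to_numpy() > theta_met).mean())


def burden_distribution(cohort: CohortResult, t: float,
                        bin_edges: np.ndarray | None = None) -> pd.DataFrame:
    """Histogram of total tumor burden across the cohort at time ``t``."""
    idx = int(np.argmin(np.abs(cohort.grid - t)))
    values = cohort.burden[:, idx]
    if bin_edges is None:
        bin_edges = np.linspace(0.0, max(float(values.max()), 1e-9), 21)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    counts, _ = np.histogram(np.clip(values, bin_edges[0], bin_edges[-1]),
                             bins=bin_edges)
    return pd.DataFrame({
        "bin_left": bin_edges[:-1],
        "bin_right": bin_edges[1:],
        "count": counts,
    })


def metabolism_experiment(p: ModelParameters, k_e_values: dict[str, float],
                          schedules: list[DosingSchedule],
                          cohort_cfg: CohortConfig
                          ) -> dict[str, tuple[CohortResult, pd.DataFrame]]:
    """Matched-seed cohorts for patient subclasses with different metabolism.

    ``k_e_values`` maps subclass labels (e.g. low/medium/high) to metabolic
    rates; every subclass shares ``cohort_cfg.base_seed`` so curves differ
    only through drug elimination.  Returns per-subclass cohort results and
    survival curves.
    """
    out: dict[str, tuple[CohortResult, pd.DataFrame]] = {}
    for label, k_e in k_e_values.items():
        cohort = simulate_cohort(p.replace(k_e=float(k_e)), schedules, cohort_cfg)
        out[label] = (cohort, survival_curve(cohort))
    return out
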