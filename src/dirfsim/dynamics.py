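"""Single-patient jump-diffusion dynamics.

The state of one virtual patient couples four cell populations to up to
three drug concentrations.  Sensitive and resistant tumor cells grow
logistically toward a shared, vasculature-dependent carrying capacity;
sensitive cells mutate to resistant at rate ``u`` and die under drug
pressure; new metastatic cells grow logistically on their own capacity;
angiogenic cells are stimulated by tumor load and inhibited by a surface
term ``C_T^(2/3)``.  Continuous stochasticity enters through independent
Wiener processes with multiplicative amplitudes; dissemination events are
driven by one shared nonhomogeneous Poisson process whose intensity is
modulated by DIRF and vasculature.  At each jump a fraction of sensitive
and resistant cells transfers to the metastatic compartment (the sensitive
fraction discounted by a drug-survival factor) and existing metastases
self-seed by a factor ``eps``.

Integration uses a jump-adapted Euler–Maruyama scheme: the regular time
grid is augmented with exactly sampled jump times (Ogata thinning against
the analytic intensity bound ``lambda0 * (1 + a_L)``), diffusion is
integrated between jumps, and every component is truncated at zero after
each update, which makes zero absorbing for the metastatic compartment in
the absence of jumps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig, DosingSchedule, ModelParameters
from .microenvironment import RateSet, evaluate_rates

__all__ = [
    "PatientState",
    "PatientTrajectory",
    "drift",
    "sample_jump_times",
    "apply_jump",
    "simulate_patient",
]

_TOL = 1e-12


@dataclass(frozen=True)
class PatientState:
    """Instantaneous state of one virtual patient."""

    t: float
    C_S: float
    C_R: float
    C_M: float
    C_K: float
    D_B: float = 0.0
    D_M: float = 0.0
    D_P: float = 0.0
    F_eff: float = 0.0


@dataclass
class PatientTrajectory:
    """States of one patient on the union of the regular grid and jump times."""

    t: np.ndarray
    C_S: np.ndarray
    C_R: np.ndarray
    C_M: np.ndarray
    C_K: np.ndarray
    D_B: np.ndarray
    D_M: np.ndarray
    D_P: np.ndarray
    F_eff: np.ndarray
    is_regular: np.ndarray          # True at regular-grid nodes
    jump_times: np.ndarray
    seed: object = None
    progressed: bool = False
    progression_time: float | None = None

    def total(self) -> np.ndarray:
        """Total tumor burden ``C_S + C_R + C_M`` at every node."""
        return self.C_S + self.C_R + self.C_M

    def regular(self) -> "PatientTrajectory":
        """Restrict to the regular grid (drop jump-only nodes)."""
        m = self.is_regular
        return PatientTrajectory(
            t=self.t[m], C_S=self.C_S[m], C_R=self.C_R[m], C_M=self.C_M[m],
            C_K=self.C_K[m], D_B=self.D_B[m], D_M=self.D_M[m], D_P=self.D_P[m],
            F_eff=self.F_eff[m], is_regular=self.is_regular[m],
            jump_times=self.jump_times, seed=self.seed,
            progressed=self.progressed, progression_time=self.progression_time,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.t, "C_S": self.C_S, "C_R": self.C_R,
            "C_M": self.C_M, "C_K": self.C_K, "D_B": self.D_B,
            "D_M": self.D_M, "D_P": self.D_P, "F_eff": self.F_eff,
        })

    def sidecar(self) -> dict:
        """JSON-serializable metadata (seed, jump times, progression flags)."""
        return {
            "seed": _describe_seed(self.seed),
            "jump_times": [float(x) for x in self.jump_times],
            "progressed": bool(self.progressed),
            "progression_time": (None if self.progression_time is None
                                 else float(self.progression_time)),
        }

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False, float_format="%.10g")
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.sidecar(), indent=2) + "\n")


def _describe_seed(seed: object) -> object:
    if isinstance(seed, np.random.SeedSequence):
        return {"entropy": int(seed.entropy),
                "spawn_key": [int(k) for k in seed.spawn_key]}
    return seed


def drift(state: PatientState, rates: RateSet, p: ModelParameters
          ) -> tuple[float, float, float, float]:
    """Deterministic increments per unit time for ``(C_S, C_R, C_M, C_K)``.

    Logistic growth of sensitive and resistant cells toward the shared
    capacity ``K_C``, mutation flux ``u*C_S`` from sensitive to resistant,
    drug-induced death ``d_S*C_S``, independent logistic growth of
    metastases, and tumor-stimulated / tumor-inhibited vessel dynamics.
    When ``K_C == 0`` (no vasculature) the logistic factor degenerates; by
    convention the growth term then becomes pure decay at the growth rate.
    """
    C_S, C_R, C_M, C_K = state.C_S, state.C_R, state.C_M, state.C_K
    if rates.K_C > 0:
        lg = 1.0 - (C_S + C_R) / rates.K_C
    else:
        lg = -1.0
    dC_S = rates.r_S * C_S * lg - p.u * C_S - rates.d_S * C_S
    dC_R = rates.r_R * C_R * lg + p.u * C_S
    dC_M = p.r_M * C_M * (1.0 - C_M / p.K_M)
    C_T = C_S + C_R + C_M
    stim = C_T / (p.K_V + C_T) if C_T > 0 else 0.0
    dC_K = p.r_K * C_K * (1.0 - C_K / p.K_K) * stim - p.d_K * C_T ** (2.0 / 3.0) * C_K
    return dC_S, dC_R, dC_M, dC_K


def sample_jump_times(intensity_path: tuple[np.ndarray, np.ndarray],
                      horizon: float, seed) -> np.ndarray:
    """Sample a nonhomogeneous Poisson process by thinning.

    ``intensity_path`` is ``(times, values)`` describing a piecewise-constant
    intensity (``values[i]`` holds on ``[times[i], times[i+1])``, the last
    value extending to ``horizon``).  Candidates arrive at the constant bound
    ``max(values)`` and are accepted with probability ``lam(t)/bound``.
    Deterministic given ``seed``.
    """
    t_grid = np.asarray(intensity_path[0], dtype=float)
    lam = np.asarray(intensity_path[1], dtype=float)
    if t_grid.ndim != 1 or lam.shape != t_grid.shape:
        raise ValueError("intensity path must be two equal-length 1-D arrays")
    if np.any(lam < 0):
        raise ValueError("intensity must be >= 0 everywhere")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    bound = float(lam.max(initial=0.0))
    if bound == 0.0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    times: list[float] = []
    t = 0.0
    while True:
        t += rng.standard_exponential() / bound
        if t >= horizon:
            break
        idx = int(np.searchsorted(t_grid, t, side="right")) - 1
        idx = max(idx, 0)
        if rng.random() * bound < lam[idx]:
            times.append(t)
    return np.asarray(times)


def apply_jump(state: PatientState, rates: RateSet, p: ModelParameters
               ) -> PatientState:
    """Apply one dissemination event to the state.

    A fraction ``beta_S`` of sensitive cells and ``beta_R`` (DIRF-modulated)
    of resistant cells leave the primary compartments; sensitive emigrants
    are thinned by the drug-survival factor ``s_D = 1 - d_S/(d_S0 + d_maxB +
    d_maxM)`` (clamped to [0, 1]) before seeding the metastatic compartment,
    resistant emigrants seed it in full, and existing metastases self-seed
    by ``eps * C_M``.  With ``eps = 0`` and no drug the event conserves total
    cell number.
    """
    loss_S = p.beta_S * state.C_S
    loss_R = rates.beta_R * state.C_R
    denom = p.d_S0 + p.d_maxB + p.d_maxM
    s_D = 1.0 - rates.d_S / denom if denom > 0 else 1.0
    s_D = min(1.0, max(0.0, s_D))
    gain_M = loss_S * s_D + loss_R + p.eps * state.C_M
    return PatientState(
        t=state.t,
        C_S=state.C_S - loss_S,
        C_R=state.C_R - loss_R,
        C_M=state.C_M + gain_M,
        C_K=state.C_K,
        D_B=state.D_B, D_M=state.D_M, D_P=state.D_P, F_eff=state.F_eff,
    )


def simulate_patient(p: ModelParameters, schedules: list[DosingSchedule],
                     cohort_cfg: CohortConfig, seed) -> PatientTrajectory:
    """Integrate one patient trajectory with the jump-adapted Euler scheme.

    ``seed`` may be an integer or a ``numpy.random.SeedSequence``; three
    independent child streams drive pharmacokinetic noise, cellular
    diffusion, and the jump process, so the realization is bit-reproducible.

    The inner loop inlines the rate arithmetic of
    :mod:`dirfsim.microenvironment` and :func:`drift` for speed; those module
    functions remain the single authoritative definitions and the recorded
    ``F_eff`` path is reproducible from them node by node.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pk_ss, diff_ss, jump_ss = ss.spawn(3)
    rng_pk = np.random.default_rng(pk_ss)
    rng_diff = np.random.default_rng(diff_ss)
    rng_jump = np.random.default_rng(jump_ss)

    dt = float(cohort_cfg.dt)
    horizon = float(cohort_cfg.horizon)
    n_reg = int(math.ceil(horizon / dt - 1e-9))

    sched_map: dict[str, DosingSchedule] = {}
    for s in schedules:
        if s.drug in sched_map:
            raise ValueError(f"duplicate schedule for drug {s.drug}")
        sched_map[s.drug] = s

    def _sched_tuple(drug: str) -> tuple[float, float, float, float]:
        s = sched_map.get(drug)
        if s is None or s.dose == 0:
            return (0.0, 1.0, 1.0, 0.0)  # never delivers
        return (float(s.dose), float(s.days_on),
                float(s.days_on + s.days_off), float(s.horizon))

    doseB, onB, perB, hB = _sched_tuple("BRAF_I")
    doseM, onM, perM, hM = _sched_tuple("MEK_I")
    doseP, onP, perP, hP = _sched_tuple("PI3K_I")

    # local bindings of every parameter used in the hot loop
    r_S0, r_R0, r_M, r_K = p.r_S0, p.r_R0, p.r_M, p.r_K
    K_Cmax, K_M, K_K, K_A = p.K_Cmax, p.K_M, p.K_K, p.K_A
    u, d_S0, d_maxB, d_maxM = p.u, p.d_S0, p.d_maxB, p.d_maxM
    K_B, K_Mi, K_P = p.K_B, p.K_Mi, p.K_P
    V_FB, V_FM, K_FB, K_FM, d_F = p.V_FB, p.V_FM, p.K_FB, p.K_FM, p.d_F
    a_S, a_R, K_rS, K_rR = p.a_S, p.a_R, p.K_rS, p.K_rR
    alpha, K_beta, a_L, K_L, K_V = p.alpha, p.K_beta, p.a_L, p.K_L, p.K_V
    beta_S, beta_R0, lambda0, eps = p.beta_S, p.beta_R0, p.lambda0, p.eps
    d_K_coef, k_e, sigma_D = p.d_K, p.k_e, p.sigma_D
    s1, s2, s3 = p.sigma_1, p.sigma_2, p.sigma_3
    if d_F <= 0:
        raise ValueError("simulate_patient requires d_F > 0 (DIRF quasi-steady state)")

    # pre-drawn Gaussian increments; refilled if jump candidates extend the mesh
    cap = n_reg + 64
    z_pk = rng_pk.standard_normal(3 * cap).tolist()
    z_df = rng_diff.standard_normal(3 * cap).tolist()
    zi = 0

    lam_bar = lambda0 * (1.0 + a_L)
    next_cand = (rng_jump.standard_exponential() / lam_bar
                 if lam_bar > 0 else math.inf)

    C_S, C_R, C_M_, C_K = p.C_S0, p.C_R0, p.C_M0, p.C_K0
    D_B = D_M = D_P = p.D0

    rec_t = [0.0]
    rec = [(C_S, C_R, C_M_, C_K, D_B, D_M, D_P)]
    rec_reg = [True]
    jump_times: list[float] = []

    t = 0.0
    k_reg = 0
    while k_reg < n_reg:
        t_reg = (k_reg + 1) * dt
        if t_reg > horizon:
            t_reg = horizon
        if next_cand < t_reg - _TOL:
            t_next, at_candidate = next_cand, True
        else:
            t_next, at_candidate = t_reg, False
        h = t_next - t
        if h < 0.0:
            h = 0.0

        # ---- delivery rates at time t ----
        vB = doseB if (t < hB and t % perB < onB) else 0.0
        vM = doseM if (t < hM and t % perM < onM) else 0.0
        vP = doseP if (t < hP and t % perP < onP) else 0.0

        # ---- effective rates at the current state (mirrors microenvironment) ----
        F = (V_FB * D_B / (K_FB + D_B) + V_FM * D_M / (K_FM + D_M)) * C_S / d_F
        F_eff = F * K_P / (K_P + D_P)
        hF_S = F_eff / (K_rS + F_eff) if F_eff > 0 else 0.0
        hF_R = F_eff / (K_rR + F_eff) if F_eff > 0 else 0.0
        r_S = r_S0 * (1.0 + a_S * hF_S)
        r_R = r_R0 * (1.0 + a_R * hF_R)
        d_S = d_S0
        if D_B > 0:
            d_S += d_maxB * D_B / (K_B + D_B)
        if D_M > 0:
            d_S += d_maxM * D_M / (K_Mi + D_M)
        K_C = K_Cmax * C_K / (K_A + C_K) if C_K > 0 else 0.0

        # ---- drift (mirrors dynamics.drift) ----
        lg = 1.0 - (C_S + C_R) / K_C if K_C > 0 else -1.0
        dC_S = r_S * C_S * lg - u * C_S - d_S * C_S
        dC_R = r_R * C_R * lg + u * C_S
        dC_M = r_M * C_M_ * (1.0 - C_M_ / K_M)
        C_T = C_S + C_R + C_M_
        stim = C_T / (K_V + C_T) if C_T > 0 else 0.0
        dC_K = r_K * C_K * (1.0 - C_K / K_K) * stim - d_K_coef * C_T ** (2.0 / 3.0) * C_K

        # ---- Euler–Maruyama update, truncated at zero ----
        if zi + 3 > len(z_pk):
            z_pk.extend(rng_pk.standard_normal(3 * 256).tolist())
            z_df.extend(rng_diff.standard_normal(3 * 256).tolist())
        sq = math.sqrt(h)
        D_B += (-k_e * D_B + vB) * h + sigma_D * D_B * sq * z_pk[zi]
        D_M += (-k_e * D_M + vM) * h + sigma_D * D_M * sq * z_pk[zi + 1]
        D_P += (-k_e * D_P + vP) * h + sigma_D * D_P * sq * z_pk[zi + 2]
        C_S += dC_S * h + s1 * C_S * sq * z_df[zi]
        C_R += dC_R * h + s2 * C_R * sq * z_df[zi + 1]
        C_M_ += dC_M * h + s3 * C_M_ * sq * z_df[zi + 2]
        C_K += dC_K * h
        zi += 3
        if D_B < 0.0: D_B = 0.0
        if D_M < 0.0: D_M = 0.0
        if D_P < 0.0: D_P = 0.0
        if C_S < 0.0: C_S = 0.0
        if C_R < 0.0: C_R = 0.0
        if C_M_ < 0.0: C_M_ = 0.0
        if C_K < 0.0: C_K = 0.0
        t = t_next

        if at_candidate:
            # Ogata thinning: accept with probability lam(state)/lam_bar
            rates = evaluate_rates(C_S, C_K, D_B, D_M, D_P, p)
            if rng_jump.random() * lam_bar < rates.lam:
                post = apply_jump(
                    PatientState(t=t, C_S=C_S, C_R=C_R, C_M=C_M_, C_K=C_K,
                                 D_B=D_B, D_M=D_M, D_P=D_P, F_eff=rates.F_eff),
                    rates, p)
                C_S, C_R, C_M_, C_K = post.C_S, post.C_R, post.C_M, post.C_K
                jump_times.append(t)
                rec_t.append(t)
                rec.append((C_S, C_R, C_M_, C_K, D_B, D_M, D_P))
                rec_reg.append(False)
            next_cand += rng_jump.standard_exponential() / lam_bar
        else:
            k_reg += 1
            rec_t.append(t)
            rec.append((C_S, C_R, C_M_, C_K, D_B, D_M, D_P))
            rec_reg.append(True)
            total = C_S + C_R + C_M_
            if not math.isfinite(total + C_K + D_B + D_M + D_P):
                raise RuntimeError(
                    f"non-finite state at t={t:.4f}: C_S={C_S}, C_R={C_R}, "
                    f"C_M={C_M_}, C_K={C_K}, D=({D_B},{D_M},{D_P})")

    arr = np.asarray(rec)
    t_arr = np.asarray(rec_t)
    C_S_a, C_R_a, C_M_a, C_K_a = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    D_B_a, D_M_a, D_P_a = arr[:, 4], arr[:, 5], arr[:, 6]
    # effective DIRF recomputed vectorized at each recorded node
    F_a = (p.V_FB * D_B_a / (p.K_FB + D_B_a)
           + p.V_FM * D_M_a / (p.K_FM + D_M_a)) * C_S_a / p.d_F
    F_eff_a = F_a * p.K_P / (p.K_P + D_P_a)

    traj = PatientTrajectory(
        t=t_arr, C_S=C_S_a, C_R=C_R_a, C_M=C_M_a, C_K=C_K_a,
        D_B=D_B_a, D_M=D_M_a, D_P=D_P_a, F_eff=F_eff_a,
        is_regular=np.asarray(rec_reg, dtype=bool),
        jump_times=np.asarray(jump_times), seed=ss,
    )
    total = traj.total()
    crossed = np.nonzero(total > p.theta_prog)[0]
    if crossed.size:
        traj.progressed = True
        traj.progression_time = float(t_arr[crossed[0]])
    return traj
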