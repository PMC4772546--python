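"""Drug- and DIRF-dependent rate functions.

Drug-sensitive cells under BRAF/MEK inhibition secrete soluble resistance
factors (DIRF, e.g. IGF and HGF) into the microenvironment.  Secretion
follows Michaelis–Menten kinetics in drug concentration; because secretion
and degradation are fast compared with cellular population dynamics, the
DIRF level is taken at quasi-steady state.  A PI3K inhibitor attenuates the
downstream action of DIRF through an inhibitory Hill factor, and the
effective DIRF level modulates the growth rates of sensitive and resistant
cells, the resistant dissemination fraction and the metastasis (jump)
intensity through saturating increments.  Vasculature enters twice: the
tumor carrying capacity saturates in the angiogenic cell number, and the
jump intensity carries a saturating vessel factor so that it stays bounded.

The rate-modulation forms here are reconstructions from the qualitative
model description (see docs/methods.md); they are deliberately isolated in
this module so alternative functional forms can be swapped without touching
the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import ModelParameters

__all__ = [
    "RateSet",
    "death_rate",
    "dirf_ode_rhs",
    "dirf_qss",
    "effective_dirf",
    "modulated_rates",
    "carrying_capacity",
    "evaluate_rates",
]


@dataclass(frozen=True)
class RateSet:
    """Effective rates at one instant of the simulation.

    ``r_S``/``r_R`` are the DIRF-modulated growth rates (1/day), ``d_S`` the
    drug-dependent death rate of sensitive cells, ``beta_R`` the effective
    resistant dissemination fraction (clamped to [0, 1]), ``lam`` the
    metastasis jump intensity (events/day), ``K_C`` the vasculature-dependent
    tumor carrying capacity and ``F_eff`` the PI3K-attenuated DIRF level.
    """

    r_S: float
    r_R: float
    d_S: float
    beta_R: float
    lam: float
    K_C: float
    F_eff: float


def death_rate(D_B: float, D_M: float, p: ModelParameters) -> float:
    """Death rate of sensitive cells under BRAF-I and MEK-I.

    ``d_S = d_S0 + d_maxB*D_B/(K_B+D_B) + d_maxM*D_M/(K_Mi+D_M)``; the two
    drug terms are additive saturating Hill functions, each half-maximal at
    its (dimensionless, unit) Michaelis constant.
    """
    if D_B < 0 or D_M < 0:
        raise ValueError("drug concentrations must be >= 0")
    dS = p.d_S0
    if D_B > 0:
        dS += p.d_maxB * D_B / (p.K_B + D_B)
    if D_M > 0:
        dS += p.d_maxM * D_M / (p.K_Mi + D_M)
    return dS


def dirf_ode_rhs(F: float, D_B: float, D_M: float, C_S: float,
                 p: ModelParameters) -> float:
    """Right-hand side of the DIRF balance equation.

    ``dF/dt = [V_FB*D_B/(K_FB+D_B) + V_FM*D_M/(K_FM+D_M)]*C_S - d_F*F``:
    Michaelis–Menten secretion by sensitive cells under either drug, minus
    first-order degradation.
    """
    if min(F, D_B, D_M, C_S) < 0:
        raise ValueError("dirf_ode_rhs: all arguments must be >= 0")
    secretion = (p.V_FB * D_B / (p.K_FB + D_B)
                 + p.V_FM * D_M / (p.K_FM + D_M)) * C_S
    return secretion - p.d_F * F


def dirf_qss(D_B: float, D_M: float, C_S: float, p: ModelParameters) -> float:
    """Quasi-steady-state DIRF concentration (the root of ``dirf_ode_rhs``).

    Valid because secretion/degradation equilibrate on a timescale of
    minutes, far faster than cellular dynamics (days).  Requires ``d_F > 0``.
    """
    if p.d_F <= 0:
        raise ValueError("dirf_qss requires d_F > 0")
    if min(D_B, D_M, C_S) < 0:
        raise ValueError("dirf_qss: all arguments must be >= 0")
    return (p.V_FB * D_B / (p.K_FB + D_B)
            + p.V_FM * D_M / (p.K_FM + D_M)) * C_S / p.d_F


def effective_dirf(F: float, D_P: float, p: ModelParameters) -> float:
    """PI3K-I attenuation of DIRF action: ``F_eff = F * K_P/(K_P + D_P)``.

    The PI3K inhibitor blocks the DIRF-stimulated PI3K/AKT signal in
    resistant cells, so it scales down every downstream DIRF effect
    uniformly rather than the DIRF concentration itself.
    """
    if F < 0 or D_P < 0:
        raise ValueError("effective_dirf: arguments must be >= 0")
    return F * p.K_P / (p.K_P + D_P)


def modulated_rates(F_eff: float, C_K: float, p: ModelParameters
                    ) -> tuple[float, float, float, float]:
    """Growth, dissemination and metastasis rates at effective DIRF ``F_eff``.

    Returns ``(r_S, r_R, beta_R, lam)`` with

    * ``r_S  = r_S0 * (1 + a_S * F_eff/(K_rS + F_eff))``
    * ``r_R  = r_R0 * (1 + a_R * F_eff/(K_rR + F_eff))``
    * ``beta_R = min(1, beta_R0 + alpha * F_eff/(K_beta + F_eff))``
    * ``lam  = lambda0 * (1 + a_L * F_eff/(K_L + F_eff)) * C_K/(K_V + C_K)``

    All four are non-decreasing and saturating in ``F_eff``; the vessel
    factor keeps the jump intensity bounded by ``lambda0 * (1 + a_L)``.
    """
    if F_eff < 0 or C_K < 0:
        raise ValueError("modulated_rates: arguments must be >= 0")
    hS = F_eff / (p.K_rS + F_eff) if F_eff > 0 else 0.0
    hR = F_eff / (p.K_rR + F_eff) if F_eff > 0 else 0.0
    hB = F_eff / (p.K_beta + F_eff) if F_eff > 0 else 0.0
    hL = F_eff / (p.K_L + F_eff) if F_eff > 0 else 0.0
    vessel = C_K / (p.K_V + C_K) if C_K > 0 else 0.0
    r_S = p.r_S0 * (1.0 + p.a_S * hS)
    r_R = p.r_R0 * (1.0 + p.a_R * hR)
    beta_R = min(1.0, p.beta_R0 + p.alpha * hB)
    lam = p.lambda0 * (1.0 + p.a_L * hL) * vessel
    return r_S, r_R, beta_R, lam


def carrying_capacity(C_K: float, p: ModelParameters) -> float:
    """Vasculature-limited tumor carrying capacity ``K_C = K_Cmax*C_K/(K_A+C_K)``."""
    if C_K < 0:
        raise ValueError("carrying_capacity: C_K must be >= 0")
    return p.K_Cmax * C_K / (p.K_A + C_K) if C_K > 0 else 0.0


def evaluate_rates(C_S: float, C_K: float, D_B: float, D_M: float, D_P: float,
                   p: ModelParameters) -> RateSet:
    """Compose the full :class:`RateSet` from one instantaneous state."""
    F = dirf_qss(D_B, D_M, C_S, p)
    F_eff = effective_dirf(F, D_P, p)
    r_S, r_R, beta_R, lam = modulated_rates(F_eff, C_K, p)
    d_S = death_rate(D_B, D_M, p)
    K_C = carrying_capacity(C_K, p)
    rs = RateSet(r_S=r_S, r_R=r_R, d_S=d_S, beta_R=beta_R,
                 lam=lam, K_C=K_C, F_eff=F_eff)
    if not all(math.isfinite(v) for v in
               (rs.r_S, rs.r_R, rs.d_S, rs.beta_R, rs.lam, rs.K_C, rs.F_eff)):
        raise ValueError(f"non-finite rates from state C_S={C_S}, C_K={C_K}")
    return rs
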