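"""Parameters, dosing schedules and cohort settings for the resistance simulator.

The model follows four interacting cell populations in a virtual patient with
metastatic, BRAF-mutant melanoma under targeted therapy: drug-sensitive tumor
cells (``C_S``), drug-resistant tumor cells (``C_R``), new metastatic cells
seeded after therapy start (``C_M``) and angiogenic/vascular cells (``C_K``),
coupled to first-order pharmacokinetics for up to three inhibitors (BRAF-I,
MEK-I, PI3K-I) and to a secreted drug-induced resistance factor (DIRF) that
feeds back on growth, dissemination and metastasis.

Units and conventions
---------------------
* cell numbers are relative, in units of 1e8 cells;
* time is measured in days;
* drug concentrations are dimensionless, normalized to the half-maximal
  inhibition constants of each drug, so ``K_B = K_Mi = K_P = 1`` by
  construction and dosing amplitudes are expressed on the same scale.

Parameter provenance
--------------------
Initial conditions (``C_S0=0.2``, ``C_R0=0.001``, ``C_K0=0.1``, ``C_M0=0``,
``D0=0``), the progression threshold (``theta_prog=1.6``), the metastatic
detectability threshold (``theta_met=1``) and the dimensionless Michaelis
constants are fixed model statements ("fixed" in ``PARAMETER_PROVENANCE``).
Every other rate constant is a calibrated repository default ("default"):
chosen once so that the shipped model exhibits its characteristic qualitative
regimes (survival separation between treated and untreated
cohorts, bimodal tumor burden at 360 days, roughly half of patients metastatic
under BRAF-I+MEK-I, and the relative synergy pattern of the two drug
combinations).  See ``docs/methods.md`` for the calibration rationale.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "DRUGS",
    "ModelParameters",
    "DosingSchedule",
    "CohortConfig",
    "ConfigError",
    "default_parameters",
    "default_schedules",
    "validate_parameters",
    "validate_schedule",
    "validate_cohort",
    "load_config",
    "save_config",
    "patient_seed",
    "PARAMETER_PROVENANCE",
]

#: Drug identifiers understood by the simulator.
DRUGS = ("BRAF_I", "MEK_I", "PI3K_I")

CONFIG_VERSION = 1


class ConfigError(ValueError):
    """Raised for malformed configuration files or invalid parameter sets."""


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set of the cellular / PK / microenvironment model.

    All rates are per day, capacities and cell numbers in units of 1e8 cells,
    drug doses and Michaelis constants for drugs dimensionless.
    """

    # -- growth --------------------------------------------------------------
    r_S0: float = 0.035     # basal growth rate of sensitive cells
    r_R0: float = 0.013     # basal growth rate of resistant cells
    r_M: float = 0.07       # growth rate of new metastatic cells
    r_K: float = 0.07       # angiogenic growth rate coefficient

    # -- capacities ----------------------------------------------------------
    K_Cmax: float = 5.0     # maximal tumor carrying capacity
    K_M: float = 1.5        # metastatic carrying capacity
    K_K: float = 1.0        # vessel carrying capacity
    K_A: float = 0.1        # Michaelis constant of vessels for tumor capacity

    # -- phenotype transition ------------------------------------------------
    u: float = 1e-4         # mutation rate sensitive -> resistant

    # -- drug-induced death --------------------------------------------------
    d_S0: float = 0.001     # basal death rate of sensitive cells
    d_maxB: float = 0.05    # maximal BRAF-I induced death rate
    d_maxM: float = 0.05    # maximal MEK-I induced death rate
    K_B: float = 1.0        # BRAF-I half-maximal inhibition (dimensionless)
    K_Mi: float = 1.0       # MEK-I half-maximal inhibition (dimensionless)
    K_P: float = 1.0        # PI3K-I half-maximal inhibition (dimensionless)

    # -- DIRF secretion and degradation --------------------------------------
    V_FB: float = 1.0       # maximal DIRF secretion rate under BRAF-I
    V_FM: float = 2.5       # maximal DIRF secretion rate under MEK-I
    K_FB: float = 1.0       # BRAF-I Michaelis constant for secretion
    K_FM: float = 1.0       # MEK-I Michaelis constant for secretion
    d_F: float = 1.0        # DIRF degradation rate

    # -- DIRF action on rates ------------------------------------------------
    a_S: float = 0.3        # DIRF amplification amplitude for r_S
    a_R: float = 0.9        # DIRF amplification amplitude for r_R
    K_rS: float = 0.1       # DIRF Michaelis constant for r_S modulation
    K_rR: float = 0.02      # DIRF Michaelis constant for r_R modulation
    alpha: float = 0.15     # regulatory coefficient of DIRF on dissemination
    K_beta: float = 0.02    # DIRF Michaelis constant for dissemination
    a_L: float = 0.2        # DIRF amplification amplitude for jump intensity
    K_L: float = 0.02       # DIRF Michaelis constant for jump intensity
    K_V: float = 0.05       # vessel Michaelis constant (metastasis + angiogenic drive)

    # -- dissemination / metastasis jumps ------------------------------------
    beta_S: float = 0.005   # dissemination fraction of sensitive cells per jump
    beta_R0: float = 0.01   # basal dissemination fraction of resistant cells
    lambda0: float = 0.0027  # basal metastasis (jump) intensity, events/day
    eps: float = 0.05       # secondary-metastasis net increase per jump

    # -- angiogenesis --------------------------------------------------------
    d_K: float = 0.02       # angiogenic inhibition coefficient by tumor cells

    # -- pharmacokinetics ----------------------------------------------------
    k_e: float = 1.0        # drug metabolic (elimination) rate
    sigma_D: float = 0.05   # PK multiplicative noise amplitude

    # -- diffusion amplitudes ------------------------------------------------
    sigma_1: float = 0.08   # diffusion amplitude for C_S
    sigma_2: float = 0.08   # diffusion amplitude for C_R
    sigma_3: float = 0.05   # diffusion amplitude for C_M

    # -- initial conditions --------------------------------------------------
    C_S0: float = 0.2
    C_R0: float = 0.001
    C_K0: float = 0.1
    C_M0: float = 0.0
    D0: float = 0.0

    # -- thresholds ----------------------------------------------------------
    theta_prog: float = 1.6  # progression threshold on total tumor cells
    theta_met: float = 1.0   # metastatic-detectability threshold

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


#: Whether each parameter value is a fixed model statement ("fixed") or a
#: calibrated repository default ("default").
PARAMETER_PROVENANCE: dict[str, str] = {
    f.name: "default" for f in fields(ModelParameters)
}
PARAMETER_PROVENANCE.update(
    {name: "fixed" for name in (
        "C_S0", "C_R0", "C_K0", "C_M0", "D0",
        "theta_prog", "theta_met",
        "K_B", "K_Mi", "K_P",   # unity by dimensionless-dose construction
    )}
)


@dataclass(frozen=True)
class DosingSchedule:
    """Repeating on/off dosing pattern for one drug.

    ``dose`` is the dimensionless delivery amplitude ``v`` applied on every
    "on" day; the pattern repeats with period ``days_on + days_off`` until
    ``horizon`` days, after which delivery stops.  ``days_off = 0`` encodes
    continuous daily dosing.
    """

    drug: str
    dose: float
    days_on: float = 21.0
    days_off: float = 7.0
    horizon: float = 360.0

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "dose": float(self.dose),
            "days_on": float(self.days_on),
            "days_off": float(self.days_off),
            "horizon": float(self.horizon),
        }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, integration step, horizon and the seeding rule.

    Patient ``i`` of a cohort with ``base_seed = s`` draws all of its
    randomness from ``numpy.random.SeedSequence(entropy=s, spawn_key=(i,))``,
    so cohorts are reproducible and treatment arms sharing ``base_seed`` use
    common random numbers.
    """

    n_patients: int = 100
    dt: float = 0.05
    horizon: float = 360.0
    base_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_patients": int(self.n_patients),
            "dt": float(self.dt),
            "horizon": float(self.horizon),
            "base_seed": int(self.base_seed),
        }


def patient_seed(base_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-patient seed derivation: ``(base_seed, i)``."""
    return np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(index),))


def default_parameters() -> ModelParameters:
    """Return the shipped, validated default parameter set."""
    p = ModelParameters()
    violations = validate_parameters(p)
    if violations:  # pragma: no cover - defaults are constructed valid
        raise ConfigError("default parameters invalid: " + "; ".join(violations))
    return p


def default_schedules(dose_braf: float = 1.0, dose_mek: float = 0.0,
                      dose_pi3k: float = 0.0, days_on: float = 21.0,
                      days_off: float = 7.0, horizon: float = 360.0
                      ) -> list[DosingSchedule]:
    """Default therapy: BRAF-I daily for three weeks, then one week off.

    MEK-I / PI3K-I schedules are added (with the same pattern) when their
    doses are positive.
    """
    doses = {"BRAF_I": dose_braf, "MEK_I": dose_mek, "PI3K_I": dose_pi3k}
    return [
        DosingSchedule(drug, dose, days_on, days_off, horizon)
        for drug, dose in doses.items() if dose > 0 or drug == "BRAF_I"
    ]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_NONNEGATIVE = (
    "r_S0", "r_R0", "r_M", "r_K", "K_A", "d_S0", "d_maxB", "d_maxM",
    "K_B", "K_Mi", "K_P", "V_FB", "V_FM", "K_FB", "K_FM", "d_F",
    "a_S", "a_R", "K_rS", "K_rR", "alpha", "K_beta", "a_L", "K_L", "K_V",
    "lambda0", "d_K", "k_e", "sigma_D", "sigma_1", "sigma_2", "sigma_3",
    "C_S0", "C_R0", "C_K0", "C_M0", "D0", "theta_prog", "theta_met",
)
_POSITIVE = ("K_Cmax", "K_M", "K_K")
_UNIT_FRACTION = ("u", "beta_S", "beta_R0", "eps")


def validate_parameters(p: ModelParameters) -> list[str]:
    """Check every type invariant; return violations as ``"field: rule"``.

    An empty list means the parameter set is admissible.  Violations are data
    rather than exceptions so callers can report all problems at once.
    """
    out: list[str] = []
    for name in (f.name for f in fields(ModelParameters)):
        v = getattr(p, name)
        if not isinstance(v, (int, float)) or not math.isfinite(float(v)):
            out.append(f"{name}: must be a finite number")
    if out:
        return out
    for name in _NONNEGATIVE:
        if getattr(p, name) < 0:
            out.append(f"{name}: must be >= 0")
    for name in _POSITIVE:
        if getattr(p, name) <= 0:
            out.append(f"{name}: must be > 0")
    for name in _UNIT_FRACTION:
        v = getattr(p, name)
        if not 0.0 <= v <= 1.0:
            out.append(f"{name}: must be in [0, 1]")
    if p.theta_prog <= p.C_S0 + p.C_R0 + p.C_M0:
        out.append(
            "theta_prog: must exceed initial total tumor burden "
            f"C_S0+C_R0+C_M0 = {p.C_S0 + p.C_R0 + p.C_M0:g}"
        )
    return out


def validate_schedule(s: DosingSchedule) -> list[str]:
    out: list[str] = []
    if s.drug not in DRUGS:
        out.append(f"drug: unknown identifier {s.drug!r}; expected one of {DRUGS}")
    if s.dose < 0:
        out.append("dose: must be >= 0")
    if s.days_on < 0 or s.days_off < 0:
        out.append("days_on/days_off: must be >= 0")
    if s.days_on + s.days_off <= 0:
        out.append("days_on+days_off: pattern period must be > 0")
    if s.horizon <= 0:
        out.append("horizon: must be > 0")
    return out


def validate_cohort(c: CohortConfig) -> list[str]:
    out: list[str] = []
    if c.n_patients < 1:
        out.append("n_patients: must be >= 1")
    if not 0 < c.dt <= 1.0:
        out.append("dt: must satisfy 0 < dt <= 1 day")
    if c.horizon <= 0:
        out.append("horizon: must be > 0")
    if int(c.base_seed) != c.base_seed or c.base_seed < 0:
        out.append("base_seed: must be a nonnegative integer")
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _check_keys(section: str, data: dict, expected: Iterable[str]) -> None:
    expected = set(expected)
    got = set(data)
    missing = sorted(expected - got)
    unknown = sorted(got - expected)
    if missing:
        raise ConfigError(f"{section}: missing field(s): {', '.join(missing)}")
    if unknown:
        raise ConfigError(f"{section}: unknown field(s): {', '.join(unknown)}")


def load_config(path: str | Path
                ) -> tuple[ModelParameters, CohortConfig, list[DosingSchedule]]:
    """Load and validate a full run configuration from a YAML file.

    Parsing is strict: every parameter must be present and no unknown keys
    are allowed, so typos fail loudly rather than silently falling back to a
    default.  ``save_config`` followed by ``load_config`` is the identity on
    all fields.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys("config", raw, ("version", "parameters", "cohort", "schedules"))
    if raw["version"] != CONFIG_VERSION:
        raise ConfigError(
            f"config: unsupported version {raw['version']!r}; "
            f"expected {CONFIG_VERSION}"
        )
    param_names = [f.name for f in fields(ModelParameters)]
    _check_keys("parameters", dict(raw["parameters"]), param_names)
    params = ModelParameters(**{k: float(v) for k, v in raw["parameters"].items()})
    violations = validate_parameters(params)
    if violations:
        raise ConfigError("parameters: " + "; ".join(violations))

    cohort_raw = dict(raw["cohort"])
    _check_keys("cohort", cohort_raw, ("n_patients", "dt", "horizon", "base_seed"))
    cohort = CohortConfig(
        n_patients=int(cohort_raw["n_patients"]),
        dt=float(cohort_raw["dt"]),
        horizon=float(cohort_raw["horizon"]),
        base_seed=int(cohort_raw["base_seed"]),
    )
    violations = validate_cohort(cohort)
    if violations:
        raise ConfigError("cohort: " + "; ".join(violations))

    schedules: list[DosingSchedule] = []
    for i, entry in enumerate(raw["schedules"]):
        entry = dict(entry)
        _check_keys(f"schedules[{i}]", entry,
                    ("drug", "dose", "days_on", "days_off", "horizon"))
        sched = DosingSchedule(
            drug=str(entry["drug"]),
            dose=float(entry["dose"]),
            days_on=float(entry["days_on"]),
            days_off=float(entry["days_off"]),
            horizon=float(entry["horizon"]),
        )
        violations = validate_schedule(sched)
        if violations:
            raise ConfigError(f"schedules[{i}]: " + "; ".join(violations))
        schedules.append(sched)
    seen = [s.drug for s in schedules]
    if len(seen) != len(set(seen)):
        raise ConfigError("schedules: duplicate drug entries")
    return params, cohort, schedules


def save_config(path: str | Path, params: ModelParameters, cohort: CohortConfig,
                schedules: Sequence[DosingSchedule]) -> None:
    """Persist a full run configuration as YAML (inverse of ``load_config``)."""
    doc = {
        "version": CONFIG_VERSION,
        "parameters": params.to_dict(),
        "cohort": cohort.to_dict(),
        "schedules": [s.to_dict() for s in schedules],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
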