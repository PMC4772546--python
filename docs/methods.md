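# Model and methods

`dirfsim` simulates acquired resistance to targeted therapy in metastatic,
BRAF-mutant melanoma as a system of jump-diffusion stochastic differential
equations, and aggregates single-patient trajectories into virtual-cohort
endpoints: progression-free survival (PFS), end-of-study tumor-burden
distributions, metastatic fractions, Bliss combination indices over dose
grids, and parameter sensitivity coefficients.

## State variables and units

| symbol | meaning | unit |
|---|---|---|
| `C_S` | drug-sensitive tumor cells | 1e8 cells |
| `C_R` | drug-resistant tumor cells | 1e8 cells |
| `C_M` | new metastatic cells (seeded after therapy start) | 1e8 cells |
| `C_K` | angiogenic (vascular) cells | 1e8 cells |
| `D_B, D_M, D_P` | BRAF-I / MEK-I / PI3K-I concentrations | dimensionless |
| `F` | drug-induced resistance factor (DIRF) | concentration |

Time is in days.  Drug concentrations and doses are normalized to the
half-maximal inhibition constants of each drug, so `K_B = K_Mi = K_P = 1`
by construction and no extra unit parameters enter the model.

## Dynamics

**Pharmacokinetics.**  Each drug follows one-compartment kinetics,
`dD = (-k_e D + v(t)) dt + sigma_D D dW`, where `v(t)` is the delivery
amplitude of a repeating on/off pattern (default: daily dosing for 21 days
followed by 7 days off).  The noise is multiplicative so the zero state is
preserved; the Euler discretization additionally truncates at zero.

**Cellular drift.**  Sensitive and resistant cells grow logistically toward
a shared, vasculature-limited capacity `K_C = K_Cmax C_K/(K_A + C_K)`;
sensitive cells mutate to resistant at rate `u` and die at the
drug-dependent rate `d_S = d_S0 + d_maxB D_B/(1+D_B) + d_maxM D_M/(1+D_M)`
(additive saturating terms — the two kinases sit on the same pathway but
the inhibitors bind independently).  Metastatic cells grow logistically on
their own capacity `K_M`.  Angiogenic cells are stimulated by total tumor
load through a saturating factor and inhibited in proportion to the tumor
surface area, `C_T^{2/3} C_K`, following the classic tumor–vasculature
interaction model.

**DIRF feedback.**  Under BRAF or MEK inhibition, sensitive cells secrete
resistance factors with Michaelis–Menten kinetics in drug concentration;
since secretion/degradation relax within minutes while cell populations
move over days, the DIRF level is taken at quasi-steady state,
`F = [V_FB D_B/(1+D_B) + V_FM D_M/(1+D_M)] C_S / d_F`.  A PI3K inhibitor
attenuates the downstream action of DIRF uniformly,
`F_eff = F/(1 + D_P)`.  `F_eff` then modulates growth, dissemination and
metastasis through saturating increments, e.g.
`r_R = r_R0 (1 + a_R F_eff/(K_rR + F_eff))`.

The rate-modulation laws admit several functional forms consistent with
the qualitative biology; this package uses multiplicative saturating
increments for the growth rates and jump intensity and an additive
saturating increment for the dissemination fraction `beta_R` (which is a
bounded fraction rather than a rate).  All four forms are isolated in
`dirfsim.microenvironment` so alternatives can be swapped without touching
the integrator.

**Jumps (metastatic dissemination).**  A single nonhomogeneous Poisson
process with intensity `lam = lambda0 (1 + a_L F_eff/(K_L+F_eff)) *
C_K/(K_V+C_K)` drives dissemination; the vessel factor keeps the intensity
bounded by `lambda0 (1 + a_L)`.  At each event a fraction `beta_S` of
sensitive and `beta_R` of resistant cells transfers to the metastatic
compartment; sensitive emigrants are thinned by the drug-survival factor
`s_D = 1 - d_S/(d_S0 + d_maxB + d_maxM)` and existing metastases self-seed
by `eps C_M` (secondary metastasis).  Tumor-size dependence enters through
the `beta * C` amplitudes; vasculature dependence through the intensity.

**Integration.**  A jump-adapted Euler–Maruyama scheme: jump candidate
times are proposed at the analytic intensity bound and accepted by Ogata
thinning against the state-dependent intensity; accepted times are inserted
exactly into the regular mesh (default `dt = 0.05` d) and diffusion is
integrated between them.  Every component is truncated at zero after each
update; zero is therefore absorbing for `C_M` in the absence of jumps,
which produces the all-or-none metastatic onset the model is built around.
Independent Wiener processes drive each cell compartment (amplitudes
`sigma_i C_i`) and each drug, per patient.

**Endpoints.**  A patient progresses at the first trajectory node where
`C_S + C_R + C_M > theta_prog = 1.6`; patients that never cross are
censored at the horizon (360 d).  Survival curves are raw counting
fractions `S(t) = #{PFS > t}/n` (no Kaplan–Meier variance machinery —
there is no loss to follow-up to correct for).  A patient is metastatic at
the horizon when `C_M > theta_met = 1`.

## Randomness and common random numbers

All randomness derives from one integer base seed.  Patient `i` uses
`SeedSequence(entropy=base_seed, spawn_key=(i,))`, split into three child
streams (PK noise, cellular diffusion, jumps).  Treatment arms that share a
base seed therefore share patient-level randomness ("common random
numbers"), which makes zero-dose effects exactly zero and reduces the
Monte-Carlo variance of effect differences, Bliss indices and sensitivity
coefficients.  Sensitivity repeats derive fresh base seeds from
`SeedSequence((base_seed, 90001, rep))`, shared between the baseline and
perturbed runs of the same repeat.

## Synergy evaluation

The effect of an arm is `E = (M0 - M)/M0`, the relative reduction of the
cohort-median total tumor burden at the evaluation time (default: the
horizon, matching the end-of-study burden distributions), with `M0` from
the matched-seed untreated control.  The Bliss combination index is
`CI = E_AB - (E_A + E_B - E_A E_B)`; positive values indicate synergy.
Monotherapy arms are simulated once per axis value and reused across the
grid.  The reference grid spans dimensionless doses 0–8: since the PI3K
attenuation is the Hill factor `1/(1+D_P)`, doses of ~4–8 are needed for
deep DIRF blockade, and the high-dose region is where the BRAF+PI3K
combination differentiates itself.  Medians (not means) over patients are
used for the burden so explosive metastatic outliers cannot dominate the
effect size; because the burden distribution is bimodal, a single cohort
median is a noisy quantile, and CI surfaces are therefore averaged over
repeats (default in the acceptance workflow: 3) with base seeds derived
from the master seed — medians within a cohort, means across repeats.

## Sensitivity analysis

Parameters are perturbed by +50% (singly, or simultaneously for a pair);
the coefficient is `S = |dQ/Q| / (dp/p)` for two outputs: the area under
the cohort-median burden curve and the area under the survival curve.
Each analysis is repeated 20 times with fresh paired seeds and reported as
mean ± sd; a parameter is flagged critical when the mean exceeds 0.2.
The normalized-relative-change form is the standard dimensionless choice
and is comparable across outputs and parameters.

## Parameter provenance and calibration

The defining model constants — initial conditions (`C_S0=0.2`,
`C_R0=0.001`, `C_K0=0.1`, `C_M0=0`, `D0=0`), thresholds (`theta_prog=1.6`,
`theta_met=1`), cohort size (100) and the unit drug Michaelis constants —
are fixed statements of the model and marked `"fixed"` in
`PARAMETER_PROVENANCE`.  The remaining rate constants are free; the
shipped defaults (marked `"default"`) were calibrated once, by hand, to
place the model in its characteristic qualitative regimes, and then
frozen:

* untreated cohorts progress early (median PFS ~2.5 months) while treated
  cohorts survive substantially longer, with combinations above
  monotherapy;
* the total-burden distribution at 360 d is bimodal, driven by all-or-none
  metastatic onset, with roughly half of BRAF-I+MEK-I patients above the
  detectability threshold;
* the BRAF-I+PI3K-I combination shows dose-dependent synergy growing
  toward high doses with a larger maximal CI than BRAF-I+MEK-I, whose
  milder synergy peaks at moderate doses.

Three calibration choices matter structurally.  First, drug-induced death
is kept sub-critical relative to DIRF-boosted regrowth over the dosing
cycle (`d_maxB = d_maxM = 0.05`/d against `r_S0 = 0.035`/d with 21/7
cycling), so arm burdens track logistic quasi-equilibria and dose-response
surfaces stay smooth; super-critical kill rates put arms near an
extinction threshold where cohort medians become nearly discontinuous in
dose and the Bliss index develops spurious spikes.  Second, the DIRF
Michaelis constants for downstream action (`K_rR`, `K_beta`, `K_L`) are
small relative to typical DIRF levels, so the resistance feedback remains
active even when the secreting sensitive population is strongly suppressed
— this is what lets PI3K-I blockade matter at high BRAF-I dose.  Third,
MEK-I is the stronger DIRF inducer (`V_FM = 2.5` vs `V_FB = 1`, both
kinases signaling to the same secretion program): the extra resistance
factor released in BRAF+MEK combination arms offsets part of the added
kill, which is what keeps that combination's synergy mild and
low-dose-weighted while leaving BRAF+PI3K untouched.

## Numerical choices and degenerate inputs

* Non-negativity by truncation at zero after each Euler step (the
  discretization convention; the multiplicative noise keeps the continuous
  dynamics non-negative already).
* `K_C = 0` (no vasculature) turns the logistic growth term into pure
  decay at the growth rate rather than dividing by zero.
* The dissemination fraction `beta_R` is clamped to 1.
* Threshold crossings are detected on trajectory nodes without
  interpolation; the jump-adapted mesh makes crossings at jumps sharp.
* `dt = 0.05` d is the default integration step (the PK relaxation rate
  `k_e = 1`/d is the fastest deterministic scale, giving `k_e dt = 0.05`);
  dose-grid scans use `dt = 0.1` with cohorts of 100 patients per arm and
  3 seed repeats, which resolves the same medians well inside the
  Monte-Carlo noise.

## What the generator does and does not emulate

Virtual cohorts differ only in random seeds: inter-patient variability
comes entirely from stochastic fluctuation (diffusion) and random
dissemination events around one shared parameter set.  Real populations
add parameter heterogeneity (the metabolism experiment, which varies `k_e`
across subclasses, is the one exception), measurement noise, dropout and
non-administrative censoring, none of which are modeled.  Passing tests
therefore demonstrate internal consistency of the stochastic model and
faithfulness of its qualitative regimes — not calibration against any
clinical dataset.  Comparisons with real survival or ctDNA series are out
of scope, as is automated parameter fitting.

## Known limitations

* No spatial structure; the microenvironment is a single well-mixed
  compartment.
* The Euler–Maruyama scheme is first-order; results at the shipped `dt`
  are discretization-converged for the reported endpoints but individual
  trajectories are not pathwise high-accuracy solutions.
* Cell numbers are continuous; extinction below one cell is not modeled,
  so arbitrarily small populations can regrow.
* PI3K-I acts only through DIRF attenuation; any direct effect on
  sensitive-cell survival is not modeled (resistant cells are the
  population with DIRF-driven PI3K/AKT over-activation).
* The rate-modulation laws are one of several functional forms consistent
  with the qualitative biology, as noted above.
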