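"""Single-patient jump-diffusion integration."""

import numpy as np
import pytest
from scipy import stats

from dirfsim import (CohortConfig, DosingSchedule, PatientState, RateSet,
                     apply_jump, drift, evaluate_rates, patient_seed,
                     sample_jump_times, simulate_patient)


def make_rates(**kw):
    base = dict(r_S=0.03, r_R=0.02, d_S=0.0, beta_R=0.01, lam=0.0,
                K_C=2.0, F_eff=0.0)
    base.update(kw)
    return RateSet(**base)


def logistic(t, C0, r, K):
    return K / (1.0 + (K / C0 - 1.0) * np.exp(-r * t))


class TestDrift:
    def test_zero_state_has_zero_drift(self, params):
        state = PatientState(t=0, C_S=0, C_R=0, C_M=0, C_K=0)
        assert drift(state, make_rates(), params) == (0.0, 0.0, 0.0, 0.0)

    def test_logistic_equilibrium(self, params):
        p = params.replace(u=0.0)
        state = PatientState(t=0, C_S=1.5, C_R=0.5, C_M=0, C_K=0.1)
        dS, dR, _, _ = drift(state, make_rates(K_C=2.0), p)
        assert dS == pytest.approx(0.0, abs=1e-14)
        assert dR == pytest.approx(0.0, abs=1e-14)

    def test_matches_finite_difference_of_logistic_solution(self, params, rng):
        # oracle: numeric derivative of the closed-form logistic solution
        p = params.replace(u=0.0)
        for _ in range(10):
            r, K, C0 = rng.uniform(0.01, 0.2), rng.uniform(1, 5), rng.uniform(0.05, 0.9)
            t = rng.uniform(1, 50)
            C = logistic(t, C0, r, K)
            h = 1e-5
            fd = (logistic(t + h, C0, r, K) - logistic(t - h, C0, r, K)) / (2 * h)
            state = PatientState(t=t, C_S=C, C_R=0, C_M=0, C_K=0.1)
            dS, *_ = drift(state, make_rates(r_S=r, K_C=K), p)
            assert dS == pytest.approx(fd, rel=1e-4)

    def test_zero_capacity_convention_is_pure_decay(self, params):
        state = PatientState(t=0, C_S=0.5, C_R=0.2, C_M=0, C_K=0.0)
        dS, dR, _, _ = drift(state, make_rates(K_C=0.0), params.replace(u=0.0))
        assert dS == pytest.approx(-0.03 * 0.5)
        assert dR == pytest.approx(-0.02 * 0.2)


class TestJumpSampling:
    def test_zero_intensity_no_jumps(self):
        path = (np.array([0.0, 100.0]), np.array([0.0, 0.0]))
        assert sample_jump_times(path, 360.0, seed=1).size == 0

    def test_poisson_mean_count(self):
        # 0.05/day over 360 d: mean count 18, checked over 1000 seeds
        path = (np.array([0.0]), np.array([0.05]))
        counts = [sample_jump_times(path, 360.0, seed=s).size
                  for s in range(1000)]
        se = np.sqrt(18.0 / 1000.0)
        assert abs(np.mean(counts) - 18.0) <= 3.0 * se

    def test_interarrivals_are_exponential(self):
        path = (np.array([0.0]), np.array([0.05]))
        times = sample_jump_times(path, 60_000.0, seed=3)
        gaps = np.diff(np.concatenate([[0.0], times]))[:2000]
        res = stats.kstest(gaps, "expon", args=(0, 1 / 0.05))
        assert res.pvalue > 0.01

    def test_thinning_respects_step_intensity(self):
        # intensity 0 on [0,180), 0.1 on [180,360): all jumps in second half
        path = (np.array([0.0, 180.0]), np.array([0.0, 0.1]))
        for s in range(50):
            times = sample_jump_times(path, 360.0, seed=s)
            assert np.all(times >= 180.0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            sample_jump_times((np.array([0.0]), np.array([-0.1])), 10.0, 1)

    def test_deterministic_given_seed(self):
        path = (np.array([0.0]), np.array([0.05]))
        a = sample_jump_times(path, 360.0, seed=9)
        b = sample_jump_times(path, 360.0, seed=9)
        assert (a == b).all()


class TestApplyJump:
    def test_zero_state_unchanged(self, params):
        state = PatientState(t=5, C_S=0, C_R=0, C_M=0, C_K=0.1)
        out = apply_jump(state, make_rates(), params)
        assert (out.C_S, out.C_R, out.C_M) == (0.0, 0.0, 0.0)

    def test_no_drug_gain_formula(self, params):
        # with d_S = d_S0 = 0 the survival factor is 1
        p = params.replace(d_S0=0.0, eps=0.05)
        state = PatientState(t=5, C_S=1.0, C_R=0.5, C_M=0.2, C_K=0.1)
        rates = make_rates(d_S=0.0, beta_R=0.02)
        out = apply_jump(state, rates, p)
        expected_gain = p.beta_S * 1.0 + 0.02 * 0.5 + 0.05 * 0.2
        assert out.C_M - state.C_M == pytest.approx(expected_gain)
        assert out.C_S == pytest.approx(1.0 - p.beta_S * 1.0)
        assert out.C_R == pytest.approx(0.5 - 0.02 * 0.5)

    def test_total_cells_conserved_without_drug_and_secondary(self, params):
        p = params.replace(d_S0=0.0, eps=0.0)
        state = PatientState(t=5, C_S=1.0, C_R=0.5, C_M=0.2, C_K=0.1)
        out = apply_jump(state, make_rates(d_S=0.0, beta_R=0.02), p)
        assert out.C_S + out.C_R + out.C_M == pytest.approx(1.7, abs=1e-15)

    def test_survival_factor_reduces_sensitive_seeding(self, params):
        # at saturating drug the sensitive emigrants do not survive transit
        d_top = params.d_S0 + params.d_maxB + params.d_maxM
        state = PatientState(t=5, C_S=1.0, C_R=0.0, C_M=0.0, C_K=0.1)
        out = apply_jump(state, make_rates(d_S=d_top), params.replace(eps=0.0))
        assert out.C_M == pytest.approx(0.0, abs=1e-15)


class TestSimulatePatient:
    def _quiet_params(self, params):
        """Noise, jumps, mutation and vessel dynamics off; C_K pinned."""
        return params.replace(sigma_1=0, sigma_2=0, sigma_3=0, sigma_D=0,
                              lambda0=0, u=0, d_S0=0, r_K=0, d_K=0)

    def test_deterministic_limit_recovers_logistic(self, params):
        p = self._quiet_params(params)
        cfg = CohortConfig(n_patients=1, dt=0.05, horizon=360.0, base_seed=0)
        traj = simulate_patient(p, [], cfg, seed=1)
        K_C = p.K_Cmax * p.C_K0 / (p.K_A + p.C_K0)
        # C_R0 is negligible but included in the joint logistic exactly
        expected = logistic(traj.t, p.C_S0 + p.C_R0, p.r_S0, K_C)
        rel = np.abs(traj.C_S + traj.C_R - expected) / expected
        assert rel.max() < 1e-2

    def test_bit_identical_given_seed(self, params, fast_cfg, braf_schedule):
        a = simulate_patient(params, [braf_schedule], fast_cfg, seed=3)
        b = simulate_patient(params, [braf_schedule], fast_cfg, seed=3)
        assert (a.C_S == b.C_S).all() and (a.t == b.t).all()
        assert (a.jump_times == b.jump_times).all()

    def test_zero_is_absorbing_for_metastases_without_jumps(self, params, fast_cfg):
        p = params.replace(lambda0=0.0)
        traj = simulate_patient(p, [], fast_cfg, seed=5)
        assert (traj.C_M == 0).all()

    def test_all_components_nonnegative_across_seeds(self, params, braf_schedule):
        cfg = CohortConfig(n_patients=1, dt=0.1, horizon=60.0, base_seed=0)
        p = params.replace(sigma_1=0.3, sigma_2=0.3, sigma_3=0.3, sigma_D=0.5)
        for s in range(10):
            traj = simulate_patient(p, [braf_schedule], cfg, seed=s)
            for arr in (traj.C_S, traj.C_R, traj.C_M, traj.C_K,
                        traj.D_B, traj.D_M, traj.D_P):
                assert (arr >= 0).all()

    def test_halving_dt_changes_endpoint_first_order(self, params):
        p = self._quiet_params(params)
        ends = {}
        for dt in (0.2, 0.1, 0.05):
            cfg = CohortConfig(n_patients=1, dt=dt, horizon=120.0, base_seed=0)
            ends[dt] = simulate_patient(p, [], cfg, seed=1).C_S[-1]
        e1 = abs(ends[0.2] - ends[0.05])
        e2 = abs(ends[0.1] - ends[0.05])
        assert e2 < e1  # error shrinks with dt

    def test_recorded_dirf_consistent_with_rate_module(self, params,
                                                       braf_schedule, fast_cfg):
        # the integrator inlines the rate arithmetic; verify against the
        # authoritative microenvironment composition at every node
        traj = simulate_patient(params, [braf_schedule], fast_cfg, seed=11)
        for i in range(0, traj.t.size, 37):
            rs = evaluate_rates(traj.C_S[i], traj.C_K[i], traj.D_B[i],
                                traj.D_M[i], traj.D_P[i], params)
            assert traj.F_eff[i] == pytest.approx(rs.F_eff, rel=1e-12)

    def test_mesh_contains_jump_times(self, params):
        p = params.replace(lambda0=0.2)  # frequent jumps
        cfg = CohortConfig(n_patients=1, dt=0.5, horizon=60.0, base_seed=0)
        traj = simulate_patient(p, [], cfg, seed=2)
        assert traj.jump_times.size > 0
        for jt in traj.jump_times:
            assert np.isclose(traj.t, jt).any()
        assert np.all(np.diff(traj.t) > 0)

    def test_duplicate_schedule_rejected(self, params, fast_cfg, braf_schedule):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_patient(params, [braf_schedule, braf_schedule],
                             fast_cfg, seed=1)

    def test_trajectory_export_roundtrip(self, params, fast_cfg, tmp_path):
        traj = simulate_patient(params, [], fast_cfg, seed=1)
        traj.write(tmp_path / "t.csv", tmp_path / "t.json")
        import json
        import pandas as pd
        df = pd.read_csv(tmp_path / "t.csv")
        assert list(df.columns) == ["time", "C_S", "C_R", "C_M", "C_K",
                                    "D_B", "D_M", "D_P", "F_eff"]
        meta = json.loads((tmp_path / "t.json").read_text())
        assert set(meta) == {"seed", "jump_times", "progressed",
                             "progression_time"}
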