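import numpy as np
import pytest

import parsimech as pm
from parsimech.datasets import FRUCTOSE_RATE, GAS_CONSTANT


class TestExperimentalDesigns:
    @pytest.mark.parametrize(
        "generator,n_obs,t_end",
        [
            (pm.generate_hypothetical, 3, 10.0),
            (pm.generate_aldol, 4, 10.0),
            (pm.generate_fructose, 3, 90.0),
        ],
    )
    def test_five_experiments_thirty_samples(self, generator, n_obs, t_end):
        data = generator(seed=1)
        assert len(data) == 5
        for exp in data:
            assert exp.n_t == 30
            assert exp.t[0] == 0.0 and exp.t[-1] == t_end
            assert exp.y.shape == (30, n_obs)
        assert data.total_points == 5 * 30 * n_obs

    def test_hypothetical_sampled_times_count(self):
        data = pm.generate_hypothetical(seed=1)
        assert sum(e.n_t for e in data) == 150

    def test_initial_conditions_match_design(self):
        data = pm.generate_hypothetical(seed=1)
        c0s = [tuple(e.C0_full) for e in data]
        assert c0s == [
            (10, 0, 2, 0, 0), (10, 2, 0, 0, 0), (10, 2, 2, 0, 0),
            (5, 0, 0, 0, 0), (10, 0, 0, 0, 0),
        ]
        assert data.experiments[0].species_names_full == ("A", "B", "C", "D", "E")

    def test_intermediates_hidden(self):
        assert pm.generate_aldol(seed=1).observed_names == ("A", "B", "C", "D")
        assert pm.generate_hypothetical(seed=1).observed_names == ("A", "B", "C")


class TestDeterminismAndNoise:
    def test_same_seed_reproduces_bitwise(self):
        a = pm.generate_aldol(seed=42)
        b = pm.generate_aldol(seed=42)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.y, eb.y)

    def test_different_seeds_share_noiseless_signal(self):
        clean = pm.generate_fructose(noiseless=True)
        n1 = pm.generate_fructose(seed=1)
        n2 = pm.generate_fructose(seed=2)
        for ec, e1, e2 in zip(clean, n1, n2):
            assert not np.array_equal(e1.y, e2.y)
            # both noisy sets scatter around the same clean trajectories
            assert abs(np.mean(e1.y - ec.y)) < 0.1
            assert abs(np.mean(e2.y - ec.y)) < 0.1

    def test_noiseless_mode_is_exact_simulation(self):
        case = pm.get_case_study("aldol")
        data = pm.generate_aldol(noiseless=True)
        for exp in data:
            res = pm.simulate(case.true_model, case.true_k, exp.C0_full, exp.t)
            assert np.allclose(exp.y, res.y[:, :4], atol=1e-9)

    def test_noise_is_zero_mean_at_scale(self):
        model = pm.matrix_to_steps([[-1, 1]], ("A", "B"))
        clean = pm.generate_generic(
            model, [0.3], [(1.0, 0.0)], (0, 10), 5000, 0.0, ("A", "B"),
            noiseless=True,
        )
        noisy = pm.generate_generic(
            model, [0.3], [(1.0, 0.0)], (0, 10), 5000, 0.15, ("A", "B"), seed=8,
        )
        resid = noisy.experiments[0].y - clean.experiments[0].y
        n = resid.size
        assert abs(resid.mean()) < 3 * 0.15 / np.sqrt(n)
        assert resid.std() == pytest.approx(0.15, rel=0.05)

    def test_negative_noisy_concentrations_are_retained(self):
        data = pm.generate_fructose(seed=3)
        assert min(exp.y.min() for exp in data) < 0.0


class TestGroundTruthDynamics:
    def test_fructose_closed_form_decay(self):
        k_eff = FRUCTOSE_RATE.k_effective
        data = pm.generate_fructose(noiseless=True)
        for exp in data:
            a0 = exp.C0_full[0]
            assert np.allclose(exp.y[:, 0], a0 * np.exp(-k_eff * exp.t), atol=1e-6)

    def test_fructose_water_to_hmf_ratio(self):
        data = pm.generate_fructose(noiseless=True)
        for exp in data:
            db = exp.y[:, 1] - exp.y[0, 1]
            dc = exp.y[:, 2] - exp.y[0, 2]
            assert np.allclose(db, 3.0 * dc, atol=1e-6)

    def test_aldol_mass_balance_through_intermediates(self):
        case = pm.get_case_study("aldol")
        t = np.linspace(0, 10, 30)
        for c0 in case.initial_condition_sets:
            res = pm.simulate(case.true_model, case.true_k, np.array(c0, float), t)
            a, c, e, f = res.y[:, 0], res.y[:, 2], res.y[:, 4], res.y[:, 5]
            consumed_a = c0[0] - a
            assert np.allclose(consumed_a, e + f + (c - c0[2]), atol=1e-6)

    def test_aldol_enolate_balance(self):
        # dE/dt + k2 E B = k1 A along the true trajectories
        case = pm.get_case_study("aldol")
        k1, k2, _ = case.true_k
        t = np.linspace(0, 10, 2001)
        res = pm.simulate(case.true_model, case.true_k, np.array((5, 10, 0, 0, 0, 0), float), t)
        a, b, e = res.y[:, 0], res.y[:, 1], res.y[:, 4]
        de_dt = np.gradient(e, t)
        # interior points only: the one-sided boundary stencil is first order
        assert np.allclose((de_dt + k2 * e * b)[1:-1], (k1 * a)[1:-1], atol=1e-3)

    def test_hypothetical_noiseless_trajectories_solve_their_odes(self):
        case = pm.get_case_study("hypothetical")
        t = np.linspace(0, 10, 2001)
        res = pm.simulate(case.true_model, case.true_k, np.array((10, 0, 0, 0, 0), float), t)
        deriv_fd = np.gradient(res.y, t, axis=0)
        deriv_rhs = np.array([
            pm.rhs(case.true_model, np.array(case.true_k), y) for y in res.y
        ])
        assert np.allclose(deriv_fd[1:-1], deriv_rhs[1:-1], atol=5e-3)


class TestArrhenius:
    def test_reference_temperature_returns_k_ref(self):
        assert FRUCTOSE_RATE.k == pytest.approx(0.9)
        assert FRUCTOSE_RATE.k_effective == pytest.approx(0.9 * 3.3e-2)

    def test_temperature_dependence_direction(self):
        hot = pm.ArrheniusRate(k_ref=0.9, E_a=5e4, T=450.0, T_ref=410.15, C_acid=3.3e-2)
        cold = pm.ArrheniusRate(k_ref=0.9, E_a=5e4, T=370.0, T_ref=410.15, C_acid=3.3e-2)
        assert hot.k > 0.9 > cold.k

    def test_gas_constant_value(self):
        assert GAS_CONSTANT == pytest.approx(8.314)


class TestRecovery:
    def test_fructose_noiseless_recovery(self):
        case = pm.get_case_study("fructose")
        data = pm.generate_fructose(noiseless=True)
        result = pm.fit(case.true_model, data, pm.FitConfig(seed=4))
        assert result.k_hat[0] == pytest.approx(case.true_k[0], rel=1e-2)

    def test_fructose_noisy_recovery_of_second_order_constant(self, fructose_data, fructose_case):
        result = pm.fit(fructose_case.true_model, fructose_data, pm.FitConfig(seed=4))
        k_second_order = result.k_hat[0] / FRUCTOSE_RATE.C_acid
        assert k_second_order == pytest.approx(0.9, rel=0.10)
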