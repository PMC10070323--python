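import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fndmc.dmc import (DMCParams, WalkerEnsemble, branch_merge, dmc_step,
                       greens_log_ratio, init_dmc_state, limited_drift,
                       run_dmc, update_trial_energy)
from fndmc.systems import builtin_system
from fndmc.trials import make_trial


def _ensemble(weights, rng=None):
    n = len(weights)
    rng = rng or np.random.default_rng(0)
    return WalkerEnsemble(
        configurations=rng.normal(size=(n, 1, 1)),
        weights=np.asarray(weights, dtype=float),
        signs=np.ones(n),
        log_magnitudes=np.zeros(n),
        local_energies=np.zeros(n),
    )


class TestLimitedDrift:
    def test_zero_drift_passes_through(self, harmonic_well):
        t = make_trial("gaussian", harmonic_well)
        v = limited_drift(t, np.zeros((1, 1, 3)), tau=0.01)
        assert np.allclose(v, 0.0)

    def test_small_drift_limit(self, harmonic_well):
        # |v| = 0.01, tau = 0.01: limiter factor 1 - |v|^2 tau / 2
        t = make_trial("gaussian", harmonic_well)
        x = np.array([[[0.01, 0.0, 0.0]]])  # grad log = -x => |v| = 0.01
        v_raw = t.grad_log(x)
        v_lim = limited_drift(t, x, tau=0.01)
        ratio = np.linalg.norm(v_lim) / np.linalg.norm(v_raw)
        assert ratio == pytest.approx(0.9999995, abs=1e-6)

    def test_large_drift_closed_form(self):
        # |v| = 100 at tau = 0.01: |v_bar| = (-1 + sqrt(1 + 200)) / 1
        t = make_trial("hydrogenic", builtin_system("H"), {"zeta": 100.0},
                       self_check=False)
        x = np.array([[[1.0, 0.0, 0.0]]])
        v_lim = limited_drift(t, x, tau=0.01)
        expected = (-1.0 + np.sqrt(1.0 + 2 * 100.0**2 * 0.01)) / (100.0 * 0.01)
        assert np.linalg.norm(v_lim) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(13.177, abs=5e-3)

    def test_magnitude_never_exceeds_raw_drift(self, he_atom, he_pade, rng):
        x = rng.normal(size=(50, 2, 3))
        raw = np.linalg.norm(he_pade.grad_log(x), axis=-1)
        lim = np.linalg.norm(limited_drift(he_pade, x, 0.02), axis=-1)
        assert np.all(lim <= raw + 1e-12)


class TestBranchMerge:
    def _params(self, **kw):
        return DMCParams(**{"tau": 0.01, "branch_threshold": 2.0, **kw})

    def test_uniform_weights_unchanged(self):
        ens = _ensemble([1.0, 1.0, 1.0, 1.0])
        out, n_branch = branch_merge(ens, np.random.default_rng(0), self._params())
        assert n_branch == 0
        assert out is ens  # no merging without branching

    def test_printed_four_walker_example(self):
        rng = np.random.default_rng(5)
        ens = _ensemble([3.0, 1.0, 0.2, 0.3])
        out, n_branch = branch_merge(ens, rng, self._params())
        assert n_branch == 1
        assert out.size == 4
        assert out.total_weight == pytest.approx(4.5, abs=1e-12)
        assert sorted(out.weights) == pytest.approx([0.5, 1.0, 1.5, 1.5])

    def test_merge_position_chosen_proportionally_to_weight(self):
        # merging weights 0.2 and 0.3: the 0.3-walker survives 60% of trials
        rng = np.random.default_rng(42)
        survivors = 0
        n_trials = 10_000
        for _ in range(n_trials):
            ens = _ensemble([3.0, 1.0, 0.2, 0.3])
            ens.configurations[2] = 20.0  # tag the 0.2 walker
            ens.configurations[3] = 30.0
            out, _ = branch_merge(ens, rng, self._params())
            merged_pos = out.configurations[out.weights == 0.5][0]
            survivors += int(np.allclose(merged_pos, 30.0))
        assert survivors / n_trials == pytest.approx(0.6, abs=0.015)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.01, max_value=10.0),
                    min_size=3, max_size=30))
    def test_weight_and_population_conserved(self, weights):
        ens = _ensemble(weights)
        out, _ = branch_merge(ens, np.random.default_rng(1), self._params())
        assert out.size == len(weights)
        assert out.total_weight == pytest.approx(sum(weights), abs=1e-12)
        assert np.all(out.weights > 0)

    def test_too_few_walkers_rejected(self):
        ens = _ensemble([3.0, 0.5])
        with pytest.raises(ValueError):
            branch_merge(ens, np.random.default_rng(0), self._params())


class TestTrialEnergyFeedback:
    def _state(self, weights, e_best):
        from fndmc.dmc import DMCState

        return DMCState(ensemble=_ensemble(weights), e_trial=e_best,
                        e_best=e_best, tau_effective=0.01, iteration=0,
                        rng=np.random.default_rng(0))

    def test_fixed_point_at_target_weight(self):
        params = DMCParams(tau=0.01, target_weight=4.0, et_damping=1.0)
        st_ = self._state([1.0] * 4, e_best=-0.5)
        assert update_trial_energy(st_, params) == pytest.approx(-0.5)

    def test_closed_form_offset(self):
        params = DMCParams(tau=0.01, target_weight=4.0, et_damping=1.0)
        st_ = self._state([np.e] * 4, e_best=-0.5)
        assert update_trial_energy(st_, params) == pytest.approx(-1.5)

    def test_feedback_is_negative_in_total_weight(self):
        params = DMCParams(tau=0.01, target_weight=4.0, et_damping=0.5)
        low = update_trial_energy(self._state([0.5] * 4, 0.0), params)
        high = update_trial_energy(self._state([2.0] * 4, 0.0), params)
        assert low > 0 > high


class TestDmcStep:
    def test_exact_trial_weights_stay_one(self, h_atom, hydrogenic_h):
        params = DMCParams(tau=0.01, n_walkers=50, seed=3).resolved(h_atom)
        state = init_dmc_state(hydrogenic_h, h_atom, params)
        state.e_trial = -0.5
        state.e_best = -0.5
        for _ in range(20):
            state = dmc_step(hydrogenic_h, h_atom, state, params)
            state.e_trial = -0.5  # hold the offset at the eigenvalue
            assert np.allclose(state.ensemble.weights, 1.0, atol=1e-12)

    def test_greens_ratio_matches_direct_reevaluation(self, he_atom, he_pade, rng):
        tau = 0.02
        x = rng.normal(size=(10, 2, 3))
        xp = x + rng.normal(scale=0.2, size=x.shape)
        got = greens_log_ratio(he_pade, x, xp, tau)
        # independent dense re-evaluation of psi^2 G ratio
        _, l0 = he_pade.sign_log(x)
        _, l1 = he_pade.sign_log(xp)
        v0 = limited_drift(he_pade, x, tau)
        v1 = limited_drift(he_pade, xp, tau)
        expect = np.empty(10)
        for i in range(10):
            g_fwd = np.exp(-np.sum((xp[i] - x[i] - v0[i] * tau) ** 2) / (2 * tau))
            g_rev = np.exp(-np.sum((x[i] - xp[i] - v1[i] * tau) ** 2) / (2 * tau))
            expect[i] = 2 * (l1[i] - l0[i]) + np.log(g_rev) - np.log(g_fwd)
        assert np.allclose(got, expect, atol=1e-10)

    def test_fixed_node_signs_never_change(self, fermions_1d, fermion_trial):
        # disable branching so walker identities persist the whole run
        params = DMCParams(tau=0.01, n_walkers=100, seed=9,
                           branch_threshold=1e6).resolved(fermions_1d)
        state = init_dmc_state(fermion_trial, fermions_1d, params)
        signs0 = state.ensemble.signs.copy()
        for _ in range(200):
            state = dmc_step(fermion_trial, fermions_1d, state, params)
            assert np.array_equal(state.ensemble.signs, signs0)


class TestRunDmc:
    def test_hydrogen_exact_node_and_trial(self, h_atom, hydrogenic_h):
        res = run_dmc(hydrogenic_h, h_atom,
                      DMCParams(tau=0.01, n_steps=1000, n_walkers=300, seed=1))
        assert res.energy.mean == pytest.approx(-0.5, abs=1e-10)
        assert res.energy.stderr < 1e-10
        assert res.state.ensemble.size == 300  # population invariant

    def test_1d_fermions_exact_antisymmetric_ground_state(self, fermions_1d,
                                                          fermion_trial):
        res = run_dmc(fermion_trial, fermions_1d,
                      DMCParams(tau=0.01, n_steps=1000, n_walkers=300, seed=2))
        assert res.energy.mean == pytest.approx(2.0, abs=max(3 * res.energy.stderr,
                                                             1e-10))

    def test_population_and_weight_stability(self, h_atom, hydrogenic_h):
        res = run_dmc(hydrogenic_h, h_atom,
                      DMCParams(tau=0.01, n_steps=2000, n_walkers=200, seed=7))
        w = np.asarray(res.state.weight_series)
        assert np.all(w > 0.5 * 200) and np.all(w < 2.0 * 200)

    def test_tau_independence_for_eigenstate_trial(self, h_atom, hydrogenic_h):
        res_a = run_dmc(hydrogenic_h, h_atom,
                        DMCParams(tau=0.02, n_steps=500, n_walkers=100, seed=3))
        res_b = run_dmc(hydrogenic_h, h_atom,
                        DMCParams(tau=0.01, n_steps=500, n_walkers=100, seed=4))
        assert res_a.energy.mean == pytest.approx(res_b.energy.mean, abs=1e-10)

    def test_determinism_given_seed(self, fermions_1d, fermion_trial):
        p = DMCParams(tau=0.02, n_steps=100, n_walkers=50, seed=12)
        r1 = run_dmc(fermion_trial, fermions_1d, p)
        r2 = run_dmc(fermion_trial, fermions_1d, p)
        assert r1.energy.mean == r2.energy.mean
        assert np.array_equal(r1.state.ensemble.configurations,
                              r2.state.ensemble.configurations)

    def test_he_nodeless_short_run_near_exact(self, he_atom):
        from fndmc.reference import helium_ground_state_energy

        t = make_trial("he_pade", he_atom, {"b": 0.15})
        res = run_dmc(t, he_atom,
                      DMCParams(tau=0.01, n_steps=2000, n_walkers=400, seed=8))
        ref = helium_ground_state_energy(order=5)
        # nodeless trial: FN-DMC is exact up to time-step bias (~0.5 mHa)
        assert res.energy.mean == pytest.approx(
            ref, abs=3 * res.energy.stderr + 1e-3)
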