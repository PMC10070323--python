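import numpy as np
import pytest

from fndmc.numeric import fd_grad_log, fd_lap_log, fd_local_energy
from fndmc.systems import builtin_system, init_walkers
from fndmc.trials import (LinearNodeTrial, SingularConfigurationError,
                          TrialConstructionError, cusp_check, local_energy,
                          make_trial, trial_catalog)


class TestLocalEnergy:
    def test_hydrogenic_trial_is_exact_eigenstate(self, h_atom, hydrogenic_h, rng):
        x = rng.normal(size=(1000, 1, 3))
        el = local_energy(hydrogenic_h, h_atom, x)
        assert np.allclose(el, -0.5, atol=1e-12)
        assert el.std() < 1e-8

    def test_gaussian_trial_exact_in_harmonic_well(self, harmonic_well, rng):
        t = make_trial("gaussian", harmonic_well)
        x = rng.normal(size=(1000, 1, 3))
        el = local_energy(t, harmonic_well, x)
        assert np.allclose(el, 1.5, atol=1e-12)

    def test_he_pade_matches_finite_difference_oracle(self, he_atom):
        t = make_trial("he_pade", he_atom, {"b": 0.5})
        x = np.array([[0.5, 0.0, 0.0], [-0.5, 0.0, 0.0]])
        el = local_energy(t, he_atom, x)
        el_fd = fd_local_energy(t, he_atom, x, h=1e-4)
        assert el == pytest.approx(el_fd, rel=1e-5)

    def test_harmonic_fermions_exact_eigenstate(self, fermions_1d, fermion_trial, rng):
        x = rng.normal(size=(500, 2, 1))
        el = local_energy(fermion_trial, fermions_1d, x)
        assert np.allclose(el, 2.0, atol=1e-10)

    def test_coincident_particles_raise(self, he_atom, he_pade):
        x = np.array([[0.3, 0.0, 0.0], [0.3, 0.0, 0.0]])
        with pytest.raises(SingularConfigurationError):
            local_energy(he_pade, he_atom, x)


class TestDerivativeConsistency:
    @pytest.mark.parametrize("name,sysname,params", [
        ("hydrogenic", "H", {}),
        ("he_pade", "He", {"b": 0.35}),
        ("slater_jastrow", "Be", {}),
        ("slater_jastrow", "C", {}),
        ("product_1s", "H2", {}),
        ("harmonic_fermions", "harmonic_fermions_1d", {}),
    ])
    def test_grad_and_lap_match_finite_differences(self, name, sysname, params):
        system = builtin_system(sysname)
        trial = make_trial(name, system, params, self_check=False)
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 20:
            x = rng.normal(scale=1.2, size=(system.n_electrons, system.dim))
            try:
                gfd = fd_grad_log(trial, x)
                lfd = fd_lap_log(trial, x)
            except ValueError:
                continue
            g = trial.grad_log(x)
            lap = trial.lap_log(x)
            assert np.allclose(g, gfd, rtol=1e-4,
                               atol=1e-5 * max(1.0, np.abs(gfd).max()))
            assert np.allclose(lap, lfd, rtol=1e-3,
                               atol=1e-3 * max(1.0, np.abs(lfd).max()))
            checked += 1


class TestAntisymmetryAndNodes:
    def test_slater_jastrow_antisymmetric_under_same_spin_swap(self, be_atom, rng):
        t = make_trial("slater_jastrow", be_atom)
        x = rng.normal(size=(4, 3))
        s, l = t.sign_log(x)
        xs = x.copy()
        xs[[0, 1]] = xs[[1, 0]]  # the two spin-up electrons
        s2, l2 = t.sign_log(xs)
        assert s2 == -s
        assert l2 == pytest.approx(l, abs=1e-12)

    def test_cross_spin_swap_not_required_to_flip(self, be_atom, rng):
        # spins are distinguishable blocks: swapping an up and a down
        # electron produces a different configuration, not a sign flip
        t = make_trial("slater_jastrow", be_atom)
        x = rng.normal(size=(4, 3))
        xs = x.copy()
        xs[[0, 2]] = xs[[2, 0]]
        _, l = t.sign_log(x)
        _, l2 = t.sign_log(xs)
        assert abs(l - l2) > 1e-10  # generically different magnitude

    def test_he_pade_nodeless_on_many_configurations(self, he_pade, rng):
        x = rng.normal(scale=2.0, size=(10_000, 2, 3))
        s, l = he_pade.sign_log(x)
        assert np.all(s == 1.0)
        assert np.all(np.isfinite(l))
        assert he_pade.nodeless and he_pade.exact_node

    def test_antisymmetry_failure_detected(self, fermions_1d):
        # a symmetric "node" trial must fail the construction self-check
        bad = LinearNodeTrial([1.0, 1.0], 0.0, n_electrons=2, dim=1)
        with pytest.raises(TrialConstructionError, match="antisymmetry"):
            bad.self_check(fermions_1d)


class TestCuspConditions:
    def test_hydrogenic_nuclear_cusp(self, h_atom, hydrogenic_h):
        rep = cusp_check(hydrogenic_h, h_atom)
        assert rep["nuclear_cusp"]["estimate"] == pytest.approx(-1.0, abs=1e-3)
        assert rep["nuclear_cusp"]["ok"]

    def test_cuspless_gaussian_flagged_on_h(self, h_atom):
        t = make_trial("gaussian", h_atom)
        rep = cusp_check(t, h_atom)
        assert not rep["nuclear_cusp"]["ok"]

    @pytest.mark.parametrize("b", [0.2, 0.5, 1.0])
    def test_he_pade_ee_cusp_is_half_for_any_b(self, he_atom, b):
        t = make_trial("he_pade", he_atom, {"b": b})
        rep = cusp_check(t, he_atom)
        assert rep["ee_cusp_antiparallel"]["estimate"] == pytest.approx(0.5, abs=1e-3)


class TestFactory:
    def test_unknown_trial_name(self, h_atom):
        with pytest.raises(KeyError):
            make_trial("nonexistent", h_atom)

    def test_catalog_names_construct(self, he_atom):
        assert "he_pade" in trial_catalog()

    def test_parameter_roundtrip(self, he_atom):
        t = make_trial("he_pade", he_atom, {"b": 0.4})
        t2 = t.with_parameters(np.array([0.25]))
        assert t2.parameters[0] == pytest.approx(0.25)
        assert t.parameters[0] == pytest.approx(0.4)  # original untouched

    def test_param_grad_matches_finite_difference(self, he_atom, rng):
        t = make_trial("he_pade", he_atom, {"b": 0.4})
        x = rng.normal(size=(5, 2, 3))
        pg = t.param_grad_log(x)
        eps = 1e-6
        lp = t.with_parameters([0.4 + eps]).sign_log(x)[1]
        lm = t.with_parameters([0.4 - eps]).sign_log(x)[1]
        assert np.allclose(pg[:, 0], (lp - lm) / (2 * eps), rtol=1e-5)
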