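import numpy as np
import pytest
from scipy.optimize import brentq

from neutraldrift.deterministic import (
    DegenerateRootError,
    bifurcation_scan,
    cytosol_rate,
    integrate_density,
    steady_states,
)
from neutraldrift.model_core import DerivedConstants, table3_params


def make_consts(rho_T, rho_star, alpha):
    return DerivedConstants(
        rho_T=rho_T, rho_star=rho_star, alpha_on_off=alpha,
        beta_on_fb=0.0, R0=rho_T / rho_star, N_star=rho_star,
    )


class TestRate:
    @pytest.mark.parametrize("rho_c,expected", [
        (0.5, 0.0),   # rho_c = rho_T fixed point at alpha = 0
        (1.0, None),  # rho_c = rho_star root, checked below
    ])
    def test_alpha_zero_roots(self, rho_c, expected):
        consts = make_consts(0.5, 1.0, 0.0)
        if rho_c <= consts.rho_T:
            assert cytosol_rate(rho_c, consts) == pytest.approx(0.0)
        else:
            # rho_star root of the quadratic factor
            assert cytosol_rate(1.0, make_consts(2.0, 1.0, 0.0)) == pytest.approx(0.0)

    def test_empty_cytosol_refills(self):
        consts = make_consts(1.5, 1.0, 0.3)
        assert cytosol_rate(0.0, consts) == pytest.approx(1.5)
        assert cytosol_rate(0.0, consts) > 0


class TestSteadyStates:
    def test_repressed_branch(self):
        res = steady_states(make_consts(0.5, 1.0, 0.0))
        assert res.roots == (0.5, 1.0)
        assert res.stability == ("stable", "unstable")
        assert res.bifurcation_type == "transcritical"
        assert res.stable_root == 0.5  # all molecules cytosolic

    def test_permissive_branch(self):
        res = steady_states(make_consts(2.0, 1.0, 0.0))
        assert res.stable_root == pytest.approx(1.0)
        # membrane density rho_T - rho_star
        assert res.roots[1] == pytest.approx(2.0)
        assert res.physical == (True, True)

    def test_degenerate_signals(self):
        with pytest.raises(DegenerateRootError):
            steady_states(make_consts(1.0, 1.0, 0.0))

    def test_imperfect_root_matches_bisection(self):
        """Near the transcritical point the closed form must agree with
        an independent root bracket to 1e-10."""
        consts = make_consts(1.0, 1.0, 1e-4)
        res = steady_states(consts)
        root = brentq(lambda r: cytosol_rate(r, consts), 0.0, 1.0, xtol=1e-14)
        assert res.stable_root == pytest.approx(root, abs=1e-10)
        assert res.bifurcation_type == "imperfect_transcritical"
        assert res.physical == (True, False)  # larger root exceeds rho_T

    def test_unique_stable_physical_root_random(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            rho_T = rng.uniform(0.01, 10)
            rho_s = rng.uniform(0.01, 10)
            alpha = 10.0 ** rng.uniform(-6, 0)
            res = steady_states(make_consts(rho_T, rho_s, alpha))
            stable_physical = [
                r for r, s, ph in zip(res.roots, res.stability, res.physical)
                if s == "stable" and ph
            ]
            assert len(stable_physical) == 1
            assert res.roots[1] > rho_T  # larger root never physical


class TestIntegration:
    def test_constant_at_fixed_point(self):
        consts = make_consts(2.0, 1.0, 0.0)
        t, rho = integrate_density(1.0, consts, t_end=5.0)
        assert np.allclose(rho, 1.0, atol=1e-7)

    @pytest.mark.parametrize("rho_T,rho_s,rho0,target", [
        (1.0, 2.0, 0.9, 1.0),    # below threshold: monotone rise to rho_T
        (2.0, 1.0, 1.1, 1.0),    # above threshold: monotone decay to rho_star
    ])
    def test_monotone_approach(self, rho_T, rho_s, rho0, target):
        consts = make_consts(rho_T, rho_s, 0.0)
        t, rho = integrate_density(rho0, consts, t_end=10.0)
        diffs = np.diff(rho)
        assert np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9)
        assert rho[-1] == pytest.approx(target, abs=1e-6)

    def test_limit_equals_stable_root_random(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            consts = make_consts(
                rng.uniform(0.1, 5), rng.uniform(0.1, 5), 10.0 ** rng.uniform(-5, -1)
            )
            res = steady_states(consts)
            expected = res.stable_root
            # linear relaxation rate |f'(r)| = (r2 - r1)/rho_star in
            # rescaled time; integrate ~30 e-folds past it
            rate = (res.roots[1] - res.roots[0]) / consts.rho_star
            t_end = 30.0 / (rate * 9.0)
            _, rho = integrate_density(consts.rho_T * rng.random(), consts, t_end=t_end)
            assert abs(rho[-1] - expected) < 1e-6

    def test_bad_initial_condition(self):
        with pytest.raises(ValueError):
            integrate_density(3.0, make_consts(1.0, 1.0, 0.1), t_end=1.0)


class TestBifurcationScan:
    def test_exchange_of_stability_at_threshold(self):
        params = table3_params(1).with_(k_on=0.0)
        grid = np.array([450.0, 899.0, 901.0, 1800.0])
        table = bifurcation_scan(params, grid)
        # below rho_star the low root is rho_T itself (f = 0)
        assert table.membrane_fraction.iloc[0] == 0.0
        assert table.membrane_fraction.iloc[1] == 0.0
        # above, stable root pins at rho_star: f = 1 - rho_star/rho_T
        assert table.membrane_fraction.iloc[3] == pytest.approx(0.5)
        below = table.iloc[1]
        above = table.iloc[2]
        assert below.root_low == pytest.approx(below.rho_T)   # stable branch = rho_T
        assert above.root_low == pytest.approx(900.0)         # stable branch = rho_star

    def test_smooth_switch_for_small_alpha(self):
        params = table3_params(1).with_(k_on=9e-3 * 1e-3 * 9)  # alpha ~ 1e-3-scale
        grid = np.linspace(100, 3600, 36)
        table = bifurcation_scan(params, grid)
        f = table.membrane_fraction.to_numpy()
        assert np.all(np.diff(f) > 0)  # strictly increasing
        assert np.all(f > 0)           # everywhere positive for alpha > 0

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            bifurcation_scan(table3_params(1), [2.0, 1.0])
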