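import numpy as np
import pytest

from neutraldrift.membrane_sim import (
    Perturbation,
    Schedule,
    StepSizeError,
    init_state,
    kymograph,
    simulate,
    step,
)
from neutraldrift.model_core import table3_params


class TestInitState:
    def test_empty_membrane(self):
        st = init_state(table3_params(100), 0.0, rng=np.random.default_rng(0))
        assert st.N_m == 0 and st.N_c == 100
        st.check()

    def test_ten_percent_seeding(self):
        st = init_state(table3_params(1000), 0.1, rng=np.random.default_rng(0))
        assert st.N_m == 100 and st.N_c == 900

    def test_clans_partition_by_arc(self):
        params = table3_params(2000)
        st = init_state(params, 1.0, n_clans=8, rng=np.random.default_rng(1))
        arcs = (st.positions / params.L * 8).astype(int) + 1
        assert np.array_equal(arcs, st.clan_ids)
        assert set(np.unique(st.clan_ids)) <= set(range(1, 9))


class TestStep:
    def test_empty_cytosol_only_loses_molecules(self):
        params = table3_params(50).with_(k_on=100.0, V_on=0.001)
        st = init_state(params, 1.0, rng=np.random.default_rng(2))
        assert st.N_c == 0
        rng = np.random.default_rng(3)
        before = st.N_m
        step(st, params, 0.001, rng)
        assert st.N_m <= before
        st.check()

    def test_recruitment_matches_binomial_oracle(self):
        """One molecule, recruitment only: membrane count after one
        step is 1 + Bernoulli(p)."""
        params = table3_params(11).with_(k_off=0.0, k_on=0.0, D_m=0.0, k_fb=5.0)
        dt = 0.0019
        p_expected = params.k_fb * 10 * dt  # N_c = 10
        rng = np.random.default_rng(5)
        total = 0
        reps = 100_000
        for _ in range(reps):
            st = init_state(params, 0.0, rng=rng)
            st.positions = np.array([0.5])
            st.clan_ids = np.array([1])
            st.N_c = 10
            step(st, params, dt, rng)
            total += st.N_m
        mean = total / reps
        se = np.sqrt(p_expected * (1 - p_expected) / reps)
        assert abs(mean - (1 + p_expected)) < 3 * se

    def test_two_state_equilibrium_without_feedback(self):
        """k_fb = 0 reduces to independent two-state molecules with
        stationary membrane fraction k_on'/(k_off + k_on')."""
        params = table3_params(100).with_(k_fb=1e-12, k_on=3.0, V_on=1.0, k_off=9.0)
        traj = simulate(
            params, Schedule(t_end=300.0, record_every=0.1),
            membrane_fraction=0.0, seed=11, record_positions=False,
        )
        frac = traj.n_mem[traj.times > 5.0].mean() / 100
        expected = 3.0 / (9.0 + 3.0)
        assert frac == pytest.approx(expected, abs=0.01)

    def test_oversized_dt_raises(self):
        params = table3_params(1000)
        st = init_state(params, 0.5, rng=np.random.default_rng(0))
        with pytest.raises(StepSizeError):
            step(st, params, 1.0, np.random.default_rng(0))


class TestSimulate:
    def test_mass_conservation_every_record(self):
        traj = simulate(table3_params(300), Schedule(t_end=5.0, record_every=0.1), seed=3)
        assert np.array_equal(traj.n_mem + traj.n_cyt, traj.n_tot)
        assert np.array_equal([len(p) for p in traj.positions], traj.n_mem)

    def test_seed_determinism(self):
        params = table3_params(400)
        sched = Schedule(t_end=3.0, record_every=0.1)
        a = simulate(params, sched, seed=9)
        b = simulate(params, sched, seed=9)
        assert np.array_equal(a.n_mem, b.n_mem)
        for pa, pb in zip(a.positions, b.positions):
            assert np.array_equal(pa, pb)

    def test_absorbing_off_state(self):
        params = table3_params(200).with_(k_on=0.0)
        traj = simulate(params, Schedule(t_end=2.0, record_every=0.1),
                        membrane_fraction=0.0, seed=0)
        assert np.all(traj.n_mem == 0)

    def test_dt_convergence(self):
        """Halving dt leaves the time-averaged membrane fraction within
        Monte-Carlo error (operator-splitting consistency)."""
        params = table3_params(150).with_(k_fb=0.24, k_on=0.05)  # N_star = 37.5
        sched = Schedule(t_end=60.0, record_every=0.2)

        def mean_frac(dt, seeds):
            vals = []
            for s in seeds:
                traj = simulate(params, sched, seed=s, dt=dt, record_positions=False)
                vals.append(traj.n_mem[traj.times > 10].mean() / 150)
            return np.mean(vals), np.std(vals) / np.sqrt(len(vals))

        m1, se1 = mean_frac(0.0025, range(10))
        m2, se2 = mean_frac(0.00125, range(10, 20))
        assert abs(m1 - m2) < 2.5 * np.hypot(se1, se2)

    def test_add_cytosol_switches_on(self):
        """Pushing N_T above N_star turns the membrane on at a level
        near N_T - N_star (the permissive-branch prediction)."""
        params = table3_params(40).with_(k_fb=0.18, k_on=0.01)  # N_star = 50
        sched = Schedule(
            t_end=40.0, record_every=0.2,
            events=((10.0, Perturbation("add_cytosol", count=110)),),
        )
        # dt sized for the post-addition molecule count
        traj = simulate(params, sched, membrane_fraction=0.0, seed=21,
                        dt=0.003, record_positions=False)
        before = traj.n_mem[(traj.times > 5) & (traj.times < 10)].mean()
        after = traj.n_mem[traj.times > 25].mean()
        assert before < 10
        assert traj.n_tot[-1] == 150
        assert after == pytest.approx(100, rel=0.25)  # ~ N_T - N_star

    def test_remove_too_many_raises_before_mutation(self):
        params = table3_params(50)
        sched = Schedule(
            t_end=2.0, record_every=0.5,
            events=((1.0, Perturbation("remove_cytosol", count=10**6)),),
        )
        with pytest.raises(ValueError, match="cannot remove"):
            simulate(params, sched, seed=0)

    def test_reseed_moves_molecules_into_window(self):
        params = table3_params(1000).with_(k_off=0.0, k_on=0.0, k_fb=1e-9, D_m=0.0)
        sched = Schedule(
            t_end=1.0, record_every=0.25,
            events=((0.5, Perturbation("reseed", fraction=0.5, window_fraction=0.1)),),
        )
        traj = simulate(params, sched, membrane_fraction=0.0, seed=13)
        assert traj.n_mem[-1] == 500
        pos = np.sort(traj.positions[-1])
        # all positions inside one 10% circular window
        gaps = np.diff(np.concatenate([pos, [pos[0] + params.L]]))
        assert gaps.max() >= 0.9 * params.L - 1e-9


class TestKymograph:
    def test_row_sums_match_membrane_counts(self):
        traj = simulate(table3_params(500), Schedule(t_end=2.0, record_every=0.2), seed=4)
        ky = kymograph(traj, 36)
        assert np.array_equal(ky.sum(axis=1), traj.n_mem)

    def test_stationary_point_molecule(self):
        params = table3_params(1).with_(k_off=0.0, k_on=0.0, k_fb=1e-9, D_m=0.0)
        traj = simulate(params, Schedule(t_end=1.0, record_every=0.2),
                        membrane_fraction=1.0, seed=0)
        ky = kymograph(traj, 12)
        col = np.nonzero(ky[0])[0]
        assert len(col) == 1
        assert np.all(ky[:, col] == 1)

    def test_requires_positions(self):
        traj = simulate(table3_params(100), Schedule(t_end=1.0, record_every=0.5),
                        seed=0, record_positions=False)
        with pytest.raises(ValueError):
            kymograph(traj, 8)
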