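import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radchemxt.radial_field import RadialGrid, total_amount
from radchemxt.solver import (
    Diagnostics,
    NumericalError,
    ScheduleError,
    SolverConfig,
    TimeStepSchedule,
    Tridiagonal,
    advance,
    assemble_cn_matrices,
    check_and_flatten,
    diffusion_step,
    reaction_increments,
    reaction_step,
    run_simulation,
    tridiagonal_solve,
)

from conftest import make_gaussian_state, make_state, simple_network


# ---------------------------------------------------------------------------
# independent dense oracle for the CN system (mirror-condition stencil
# assembled row by row, no tridiagonal machinery)
# ---------------------------------------------------------------------------

def dense_cn_oracle(D, dt, grid):
    J, bw, r = grid.n_bins, grid.bin_width, grid.bin_centers
    L = np.zeros((J, J))
    for j in range(J):
        stencil = [
            (j - 1, 1.0 / bw**2 - 1.0 / (2.0 * bw * r[j])),
            (j, -2.0 / bw**2),
            (j + 1, 1.0 / bw**2 + 1.0 / (2.0 * bw * r[j])),
        ]
        for jj, w in stencil:
            jj = min(max(jj, 0), J - 1)  # a_{-1} = a_0, a_J = a_{J-1}
            L[j, jj] += w
    M = np.eye(J) - 0.5 * D * dt * L
    N = np.eye(J) + 0.5 * D * dt * L
    return M, N


class TestAssembleCnMatrices:
    def test_zero_diffusion_degenerates_to_identity(self, small_grid):
        M, N = assemble_cn_matrices(0.0, 1.0, small_grid)
        eye = np.eye(small_grid.n_bins)
        assert np.array_equal(M.to_dense(), eye)
        assert np.array_equal(N.to_dense(), eye)

    def test_flat_vector_is_shared_eigenvector(self, small_grid):
        M, N = assemble_cn_matrices(3.0, 0.5, small_grid)
        flat = np.full(small_grid.n_bins, 7.5e-7)
        assert np.allclose(M.matvec(flat.copy()), N.matvec(flat.copy()),
                           rtol=1e-14, atol=1e-20)

    def test_matches_dense_oracle(self):
        grid = RadialGrid(25.0, 8, 1.0e3)
        for D, dt in [(2.8, 0.5), (9.46, 1.0), (0.1, 2.5)]:
            M, N = assemble_cn_matrices(D, dt, grid)
            Md, Nd = dense_cn_oracle(D, dt, grid)
            assert np.allclose(M.to_dense(), Md, rtol=1e-13)
            assert np.allclose(N.to_dense(), Nd, rtol=1e-13)
            # full propagator against dense linear algebra
            P = tridiagonal_solve(M, N.to_dense())
            P_dense = np.linalg.solve(Md, Nd)
            assert np.max(np.abs(P - P_dense)) < 1e-12

    def test_invalid_inputs(self, small_grid):
        with pytest.raises(ValueError):
            assemble_cn_matrices(-1.0, 0.5, small_grid)
        with pytest.raises(ValueError):
            assemble_cn_matrices(1.0, 0.0, small_grid)


class TestTridiagonalSolve:
    def test_identity(self):
        M = Tridiagonal(np.zeros(2), np.ones(3), np.zeros(2))
        rhs = np.array([1.0, -2.0, 3.0])
        assert np.array_equal(tridiagonal_solve(M, rhs), rhs)

    def test_known_3x3(self):
        M = Tridiagonal(np.array([1.0, 2.0]), np.array([4.0, 5.0, 6.0]),
                        np.array([1.0, 1.0]))
        rhs = np.array([1.0, 2.0, 3.0])
        expected = np.linalg.solve(M.to_dense(), rhs)
        assert np.allclose(tridiagonal_solve(M, rhs), expected, rtol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31))
    def test_random_diagonally_dominant_vs_dense(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        lower = rng.uniform(-1, 1, n - 1)
        upper = rng.uniform(-1, 1, n - 1)
        diag = 2.5 + rng.uniform(0, 1, n)
        M = Tridiagonal(lower, diag, upper)
        rhs = rng.uniform(-1, 1, n)
        x = tridiagonal_solve(M, rhs)
        x_dense = np.linalg.solve(M.to_dense(), rhs)
        assert np.max(np.abs(x - x_dense)) < 1e-10

    def test_matrix_rhs(self):
        rng = np.random.default_rng(0)
        n = 12
        M = Tridiagonal(rng.uniform(-1, 1, n - 1), 3.0 + rng.uniform(0, 1, n),
                        rng.uniform(-1, 1, n - 1))
        B = rng.uniform(-1, 1, (n, 5))
        assert np.allclose(tridiagonal_solve(M, B),
                           np.linalg.solve(M.to_dense(), B), rtol=1e-11)

    def test_zero_pivot_raises(self):
        M = Tridiagonal(np.array([1.0]), np.array([0.0, 1.0]), np.array([1.0]))
        with pytest.raises(NumericalError):
            tridiagonal_solve(M, np.array([1.0, 1.0]))

    def test_full_grid_propagator_vs_dense(self, default_grid):
        # J = 250, production settings
        D, dt = 9.46, 0.5
        M, N = assemble_cn_matrices(D, dt, default_grid)
        P = tridiagonal_solve(M, N.to_dense())
        Md, Nd = dense_cn_oracle(D, dt, default_grid)
        assert np.max(np.abs(P - np.linalg.solve(Md, Nd))) < 1e-10


class TestDiffusionStep:
    def test_flat_field_is_fixed_point(self, small_grid, default_net):
        state = make_state(small_grid, {"OH": 4.2e-7})
        before = state.fields["OH"].values.copy()
        diffusion_step(state, default_net, 0.5)
        assert np.allclose(state.fields["OH"].values, before,
                           rtol=1e-13, atol=1e-20)

    def test_flattened_fields_untouched(self, small_grid, default_net):
        state = make_state(small_grid, {"OH": 4.2e-7}, flattened=True)
        marker = state.fields["OH"].values.copy()
        diffusion_step(state, default_net, 0.5)
        assert np.array_equal(state.fields["OH"].values, marker)

    def test_second_moment_grows_by_4_D_dt(self):
        # <r^2> of a 2-D Gaussian grows by 4 D dt per step (up to O(bw^2))
        grid = RadialGrid(10.0, 200, 1.0e3)  # r_max = 2 um
        D, dt, n_steps = 2.8, 0.5, 200
        net = simple_network([], species_names=("A",), diffusion=D)
        state = make_gaussian_state(grid, "A", sigma=150.0)
        vols = grid.bin_volumes_l
        r2 = grid.bin_centers**2

        def second_moment(vals):
            w = vals * vols
            return float(np.dot(w, r2) / w.sum())

        m0 = second_moment(state.fields["A"].values)
        for _ in range(n_steps):
            diffusion_step(state, net, dt)
        m1 = second_moment(state.fields["A"].values)
        assert m1 - m0 == pytest.approx(4.0 * D * dt * n_steps, rel=0.01)

    def test_mass_conserved_over_1000_steps(self):
        grid = RadialGrid(20.0, 100, 1.0e4)
        net = simple_network([], species_names=("A",), diffusion=0.005)
        state = make_gaussian_state(grid, "A", sigma=100.0)
        m0 = total_amount(state.fields["A"], grid)
        for _ in range(1000):
            diffusion_step(state, net, 0.5)
        m1 = total_amount(state.fields["A"], grid)
        assert abs(m1 - m0) / m0 < 1e-3

    def test_nonnegativity_preserved_on_track_profile(self, default_net):
        grid = RadialGrid(20.0, 100, 1.0e4)
        diag = Diagnostics()
        state = make_gaussian_state(grid, "OH", sigma=50.0, amplitude=1e-5)
        for _ in range(500):
            diffusion_step(state, default_net, 0.5, diagnostics=diag)
        assert np.all(state.fields["OH"].values >= 0.0)
        assert diag.diffusion_clamps == 0

    def test_gaussian_matches_heat_kernel_second_order_in_bw(self):
        # free 2-D diffusion: sigma^2(t) = sigma0^2 + 2 D t; L2 error
        # decreases ~4x when bw is halved
        D, sigma0, t_total, dt = 2.0, 200.0, 2000.0, 0.5
        sigma1_sq = sigma0**2 + 2.0 * D * t_total
        errors = []
        for bw in (40.0, 20.0):
            grid = RadialGrid.from_rmax(bw, 2000.0, 1.0e3)
            net = simple_network([], species_names=("A",), diffusion=D)
            state = make_gaussian_state(grid, "A", sigma=sigma0, amplitude=1.0)
            for _ in range(int(t_total / dt)):
                diffusion_step(state, net, dt)
            r = grid.bin_centers
            analytic = (sigma0**2 / sigma1_sq) * np.exp(-(r**2) / (2 * sigma1_sq))
            err = np.sqrt(np.mean((state.fields["A"].values - analytic) ** 2))
            errors.append(err)
        ratio = errors[0] / errors[1]
        assert 2.5 < ratio < 6.5


class TestReactionIncrements:
    def test_hand_value(self, small_grid):
        # k = 1e10 /M/s, [A] = [B] = 1e-6 M, dt = 0.5 ns -> dA = -5e-12 M
        net = simple_network([(("A", "B"), ("C",), 1e10)])
        state = make_state(small_grid, {"A": 1e-6, "B": 1e-6, "C": 0.0})
        inc = reaction_increments(state, net, 0.5)
        assert np.allclose(inc["A"], -5e-12, rtol=1e-12)

    def test_zero_concentrations_zero_increments(self, small_grid, default_net):
        state = make_state(small_grid,
                           {n: 0.0 for n in default_net.species_names})
        inc = reaction_increments(state, default_net, 0.5)
        for arr in inc.values():
            assert np.all(arr == 0.0)

    def test_stoichiometry_bin_wise(self, small_grid):
        net = simple_network([(("A", "B"), ("C",), 1e10)])
        rng = np.random.default_rng(11)
        state = make_state(small_grid, {"A": 0.0, "B": 0.0, "C": 0.0})
        state.fields["A"].values = rng.uniform(0, 1e-6, small_grid.n_bins)
        state.fields["B"].values = rng.uniform(0, 1e-6, small_grid.n_bins)
        inc = reaction_increments(state, net, 0.5)
        assert np.allclose(inc["A"], inc["B"], rtol=1e-14)
        assert np.allclose(inc["A"], -inc["C"], rtol=1e-14)

    def test_continuum_reactant_enters_as_fixed_concentration(self, small_grid,
                                                              oxic_net):
        c = 1e-7
        state = make_state(small_grid,
                           {n: 0.0 for n in oxic_net.species_names})
        state.fields["e_aq-"].values[:] = c
        inc = reaction_increments(state, oxic_net, 1.0)
        k = oxic_net.find_reaction("e_aq-+O2->O2-").rate_constant
        o2 = oxic_net.continuum_concentrations["O2"]
        assert np.allclose(inc["O2-"], k * o2 * c * 1.0, rtol=1e-12)


class TestReactionStep:
    def test_second_order_kinetics_closed_form(self, small_grid):
        # A + B -> C from equal start c: 1/[A] = 1/c + k t
        c0, k_si, t_total, dt = 1e-5, 1e10, 1.0e4, 1.0
        net = simple_network([(("A", "B"), ("C",), k_si)])
        state = make_state(small_grid, {"A": c0, "B": c0, "C": 0.0})
        for _ in range(int(t_total / dt)):
            reaction_step(state, net, dt)
        k = k_si * 1e-9
        expected = 1.0 / (1.0 / c0 + k * t_total)
        assert state.fields["A"].values[0] == pytest.approx(expected, rel=1e-3)
        assert state.fields["C"].values[0] == pytest.approx(c0 - expected,
                                                            rel=1e-3)

    def test_same_species_convention_slope_2k(self, small_grid):
        # A + A -> B with event constant k: d[A]/dt = -2k[A]^2, so the
        # slope of 1/[A] against t is 2k
        c0, k_si = 1e-5, 5e9
        net = simple_network([(("A", "A"), ("B",), k_si)])
        state = make_state(small_grid, {"A": c0, "B": 0.0})
        dt, n_steps = 1.0, 10000
        times = [0.0]
        inverse = [1.0 / c0]
        for i in range(n_steps):
            reaction_step(state, net, dt)
            if (i + 1) % 1000 == 0:
                times.append((i + 1) * dt)
                inverse.append(1.0 / state.fields["A"].values[0])
        slope = np.polyfit(times, inverse, 1)[0]
        assert slope == pytest.approx(2.0 * k_si * 1e-9, rel=1e-3)
        # B produced at half the A consumption
        assert state.fields["B"].values[0] == pytest.approx(
            0.5 * (c0 - state.fields["A"].values[0]), rel=1e-9
        )

    def test_zero_rate_is_identity(self, small_grid):
        net = simple_network([(("A", "B"), ("C",), 0.0)])
        state = make_state(small_grid, {"A": 1e-6, "B": 1e-6, "C": 0.0})
        before = {n: f.values.copy() for n, f in state.fields.items()}
        reaction_step(state, net, 0.5)
        for n, f in state.fields.items():
            assert np.array_equal(f.values, before[n])

    def test_overdepletion_clamped_and_counted(self, small_grid):
        net = simple_network([(("A", "B"), ("C",), 1e14)])
        state = make_state(small_grid, {"A": 1e-6, "B": 1e-3, "C": 0.0})
        diag = Diagnostics()
        reaction_step(state, net, 10.0, diagnostics=diag)
        assert diag.reaction_clamps > 0
        assert np.all(state.fields["A"].values >= 0.0)

    def test_amount_changes_by_stoichiometric_sum(self, small_grid):
        net = simple_network([(("A", "B"), ("C",), 1e10)])
        rng = np.random.default_rng(5)
        state = make_state(small_grid, {"A": 0.0, "B": 0.0, "C": 0.0})
        state.fields["A"].values = rng.uniform(0, 1e-6, small_grid.n_bins)
        state.fields["B"].values = rng.uniform(0, 1e-6, small_grid.n_bins)
        inc = reaction_increments(state, net, 0.5)
        before = {n: state.fields[n].values.copy() for n in state.fields}
        reaction_step(state, net, 0.5)
        for n in state.fields:
            assert np.allclose(state.fields[n].values, before[n] + inc[n],
                               rtol=1e-14)


class TestAdvance:
    def test_no_reactions_flat_field_unchanged(self, small_grid):
        net = simple_network([], species_names=("A",), diffusion=2.0)
        state = make_state(small_grid, {"A": 1e-7})
        advance(state, net, 0.5)
        assert np.allclose(state.fields["A"].values, 1e-7, rtol=1e-13)
        assert state.time == 0.5

    def test_zero_diffusion_equals_pure_reactions(self, small_grid):
        net = simple_network([(("A", "B"), ("C",), 1e10)], diffusion=0.0)
        rng = np.random.default_rng(2)
        vals = {n: rng.uniform(0, 1e-6, small_grid.n_bins) for n in "ABC"}
        s1 = make_state(small_grid, {"A": 0.0, "B": 0.0, "C": 0.0})
        s2 = make_state(small_grid, {"A": 0.0, "B": 0.0, "C": 0.0})
        for n in "ABC":
            s1.fields[n].values = vals[n].copy()
            s2.fields[n].values = vals[n].copy()
        advance(s1, net, 0.5)
        reaction_step(s2, net, 0.5)
        for n in "ABC":
            assert np.allclose(s1.fields[n].values, s2.fields[n].values,
                               rtol=1e-13)

    def test_splitting_error_first_order_richardson(self):
        # halving dt should roughly halve the deviation from a fine-dt
        # reference (Lie splitting + forward Euler are O(dt))
        grid = RadialGrid(20.0, 60, 1.0e3)
        net = simple_network([(("A", "B"), ("C",), 5e10)], diffusion=3.0)

        def run(dt):
            state = make_state(grid, {"A": 0.0, "B": 0.0, "C": 0.0})
            r = grid.bin_centers
            state.fields["A"].values = 1e-4 * np.exp(-(r / 150.0) ** 2)
            state.fields["B"].values = 1e-4 * np.exp(-(r / 250.0) ** 2)
            n = int(200.0 / dt)
            for _ in range(n):
                advance(state, net, dt)
            return state.fields["C"].values.copy()

        ref = run(0.125)
        e1 = np.linalg.norm(run(1.0) - ref)
        e2 = np.linalg.norm(run(0.5) - ref)
        assert 1.5 < e1 / e2 < 3.0


class TestCheckAndFlatten:
    def test_constant_field_flattens_and_preserves_value(self, small_grid):
        state = make_state(small_grid, {"A": 3.3e-8})
        check_and_flatten(state, 0.05)
        fld = state.fields["A"]
        assert fld.flattened
        assert fld.flat_value == pytest.approx(3.3e-8, rel=1e-12)

    def test_rel_std_above_threshold_not_flattened(self, small_grid):
        state = make_state(small_grid, {"A": 0.0})
        vals = np.ones(small_grid.n_bins)
        vals[: small_grid.n_bins // 4] = 2.0  # rel std ~ 0.33
        state.fields["A"].values = vals
        check_and_flatten(state, 0.05)
        assert not state.fields["A"].flattened

    def test_example_vector_not_flattened(self):
        # [1, 1, 1, 2]: rel std = 0.433/1.25 ~ 0.346 > 0.05
        grid = RadialGrid(10.0, 4, 100.0)
        state = make_state(grid, {"A": 0.0})
        state.fields["A"].values = np.array([1.0, 1.0, 1.0, 2.0])
        rel_std = state.fields["A"].values.std() / state.fields["A"].values.mean()
        assert rel_std == pytest.approx(0.34641, rel=1e-4)
        check_and_flatten(state, 0.05)
        assert not state.fields["A"].flattened
        check_and_flatten(state, 0.5)
        assert state.fields["A"].flattened

    def test_collapse_conserves_total_amount(self, small_grid):
        rng = np.random.default_rng(8)
        state = make_state(small_grid, {"A": 0.0})
        state.fields["A"].values = 1e-7 * (1.0 + 0.01 * rng.uniform(
            -1, 1, small_grid.n_bins))
        m0 = total_amount(state.fields["A"], small_grid)
        check_and_flatten(state, 0.05)
        assert state.fields["A"].flattened
        m1 = total_amount(state.fields["A"], small_grid)
        assert abs(m1 - m0) / m0 < 1e-12

    def test_zero_field_treated_as_flat_at_zero(self, small_grid):
        state = make_state(small_grid, {"A": 0.0})
        check_and_flatten(state, 0.05)
        assert state.fields["A"].flattened
        assert state.fields["A"].flat_value == 0.0


class TestTimeStepSchedule:
    def test_default_reproduces_interval_table(self):
        sched = TimeStepSchedule.default(500.0, 2.0e6)
        assert sched.intervals == (
            (500.0, 1.0e3, 0.5),
            (1.0e3, 1.0e4, 1.0),
            (1.0e4, 1.0e5, 2.5),
            (1.0e5, 1.0e6, 5.0),
            (1.0e6, 2.0e6, 10.0),
        )

    def test_default_clipped_to_short_run(self):
        sched = TimeStepSchedule.default(500.0, 5.0e3)
        assert sched.intervals == ((500.0, 1.0e3, 0.5), (1.0e3, 5.0e3, 1.0))

    def test_gap_rejected(self):
        with pytest.raises(ScheduleError):
            TimeStepSchedule(((0.0, 10.0, 1.0), (20.0, 30.0, 1.0)))

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ScheduleError):
            TimeStepSchedule(((0.0, 10.0, 0.0),))

    def test_dt_lookup(self):
        sched = TimeStepSchedule.default(500.0, 2.0e6)
        assert sched.dt_at(500.0) == 0.5
        assert sched.dt_at(999.9) == 0.5
        assert sched.dt_at(1.0e3) == 1.0
        assert sched.dt_at(5.0e5) == 5.0
        assert sched.dt_at(1.5e6) == 10.0


class TestRunSimulation:
    def test_zero_initial_condition_runs_to_completion(self, small_grid,
                                                       default_net):
        state = make_state(small_grid,
                           {n: 0.0 for n in default_net.species_names})
        cfg = SolverConfig(t_in=500.0, t_end=2000.0, record_times=(1000.0, 2000.0))
        res = run_simulation(state, default_net, cfg)
        assert len(res.snapshots) == 2
        assert res.final_state.time == pytest.approx(2000.0)
        for fld in res.final_state.fields.values():
            assert np.all(fld.values == 0.0)
        assert res.diagnostics.reaction_clamps == 0

    def test_schedule_gap_rejected_before_starting(self, small_grid, default_net):
        with pytest.raises(ScheduleError):
            SolverConfig(
                t_in=500.0, t_end=5000.0,
                schedule=TimeStepSchedule(((500.0, 1000.0, 0.5),)),
            )

    def test_deterministic(self, small_grid, default_net):
        def one_run():
            state = make_state(
                small_grid, {n: 1e-8 for n in default_net.species_names})
            cfg = SolverConfig(t_in=500.0, t_end=1500.0, record_times=(1500.0,))
            return run_simulation(state, default_net, cfg)

        a, b = one_run(), one_run()
        for n in default_net.species_names:
            assert np.array_equal(a.final_state.fields[n].values,
                                  b.final_state.fields[n].values)

    def test_flat_state_advance_equals_homogeneous_euler(self, small_grid):
        # on a flattened state the split step is exactly bin-independent
        # homogeneous forward-Euler kinetics
        c0, k_si, dt = 1e-6, 1e10, 0.5
        net = simple_network([(("A", "B"), ("C",), k_si)], diffusion=4.0)
        state = make_state(small_grid, {"A": c0, "B": c0, "C": 0.0},
                           flattened=True)
        advance(state, net, dt)
        k = k_si * 1e-9
        expected = c0 - k * c0 * c0 * dt
        assert state.fields["A"].flat_value == pytest.approx(expected, rel=1e-14)

    def test_category_iii_stays_zero_without_oxygen(self, small_grid):
        from radchemxt.chemistry import CATEGORIES, build_default_network
        net = build_default_network(po2=0.0)
        conc = {n: 0.0 for n in net.species_names}
        for n in CATEGORIES["i"] + CATEGORIES["ii"]:
            conc[n] = 1e-7
        state = make_state(small_grid, conc, flattened=True)
        cfg = SolverConfig(t_in=500.0, t_end=1.0e4,
                           record_times=(1e3, 5e3, 1e4))
        res = run_simulation(state, net, cfg)
        for snap in res.snapshots + [res.final_state]:
            for n in CATEGORIES["iii"]:
                assert snap.fields[n].flat_value == 0.0
                assert np.all(snap.fields[n].values == 0.0)
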