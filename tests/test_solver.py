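import numpy as np
import pytest

from gliotrial import ModelParams, generate_synthetic_brain, seed_tumor
from gliotrial.geometry import BrainGeometry
from gliotrial.model_core import TumorState
from gliotrial.solver import (
    Schedule,
    advance,
    advection_term,
    diffusion_term,
    simulate,
    stable_dt,
    step,
)


def _line_geometry(n=5):
    """1 x n strip of brain voxels (1-D stencil checks)."""
    mask = np.ones((1, n), dtype=bool)
    return BrainGeometry(mask=mask, B0=mask.astype(float),
                         D=mask.astype(float), spacing=1.5)


class TestDiffusion:
    def test_uniform_field_has_zero_divergence(self, small_geom):
        I = np.where(small_geom.mask, 0.3, 0.0)
        st = TumorState(np.zeros_like(I), I, small_geom.B0.copy(),
                        np.zeros_like(I))
        out = diffusion_term(I, small_geom, st, delta=4e-3)
        assert np.allclose(out, 0.0, atol=1e-15)

    def test_three_cell_spike_is_discrete_laplacian(self):
        geom = _line_geometry(3)
        I = np.array([[0.0, 1.0, 0.0]])
        st = TumorState(np.zeros_like(I), I, geom.B0.copy(), np.zeros_like(I))
        delta, h = 2e-3, geom.spacing
        out = diffusion_term(I, geom, st, delta)
        assert out == pytest.approx(delta / h**2 * np.array([[1.0, -2.0, 1.0]]))

    def test_mass_conserving(self, small_geom, random_state):
        out = diffusion_term(random_state.I, small_geom, random_state, 4e-3)
        assert out.sum() == pytest.approx(0.0, abs=1e-12)

    def test_necrotic_core_blocks_diffusion(self):
        geom = _line_geometry(3)
        I = np.array([[0.0, 1.0, 0.0]])
        B = np.array([[1.0, 1.0, 0.05]])  # right voxel: >80% brain death
        st = TumorState(np.zeros_like(I), I, B, np.zeros_like(I))
        out = diffusion_term(I, geom, st, 2e-3)
        # flux into the dead voxel is ~1e-6 of the healthy-side flux
        assert abs(out[0, 2]) < 1e-5 * abs(out[0, 0])

    def test_negative_delta_rejected(self, small_geom, random_state):
        with pytest.raises(ValueError):
            diffusion_term(random_state.I, small_geom, random_state, -1.0)


class TestAdvection:
    def test_uniform_B_moves_nothing(self, small_geom, random_state):
        B = np.where(small_geom.mask, 1.0, 0.0)
        out = advection_term(random_state.I, B, small_geom, 1.4e-3)
        assert np.allclose(out, 0.0, atol=1e-15)

    def test_two_cell_upwind_flux(self):
        geom = _line_geometry(2)
        I = np.array([[1.0, 0.0]])
        B = np.array([[0.0, 1.0]])
        eta, h = 1.4e-3, geom.spacing
        out = advection_term(I, B, geom, eta)
        v = eta * (1.0 - 0.0) / h
        # all flux from cell 0 (donor) to cell 1, conservative
        assert out[0, 0] == pytest.approx(-v / h)
        assert out[0, 1] == pytest.approx(v / h)
        assert out.sum() == pytest.approx(0.0, abs=1e-15)

    def test_moves_up_the_brain_gradient(self):
        geom = _line_geometry(5)
        I = np.array([[0.0, 0.0, 1.0, 0.0, 0.0]])
        B = np.array([[0.0, 0.25, 0.5, 0.75, 1.0]])
        out = advection_term(I, B, geom, 1.4e-3)
        assert out[0, 3] > 0 and out[0, 2] < 0
        assert out[0, 1] == 0.0  # donor there has no cells

    def test_mass_conserving_on_random_fields(self, small_geom, random_state):
        out = advection_term(random_state.I, random_state.B, small_geom, 1.4e-3)
        assert out.sum() == pytest.approx(0.0, abs=1e-12)

    def test_positivity_under_stable_dt(self):
        rng = np.random.default_rng(8)
        geom = _line_geometry(20)
        params = ModelParams(delta=0.0, eta=1.4e-3, tau=0.0, gamma=0.0)
        dt = stable_dt(params, geom)
        I = rng.uniform(0, 1, (1, 20))
        B = rng.uniform(0, 1, (1, 20))
        for _ in range(50):
            I = I + dt * advection_term(I, B, geom, params.eta)
        assert I.min() >= -1e-14

    def test_negative_eta_rejected(self, small_geom, random_state):
        with pytest.raises(ValueError):
            advection_term(random_state.I, random_state.B, small_geom, -1.0)


class TestStableDt:
    def test_reaction_bound_dominates_at_table_rates(self, small_geom):
        params = ModelParams(delta=4e-3, eta=1.4e-3)
        dt = stable_dt(params, small_geom)
        reaction = 1.0 / (2.02 + 2.00 + 100 * 0.17)
        assert dt == pytest.approx(0.5 * reaction)
        assert 0.01 < dt < 0.05

    def test_zero_motility_leaves_reaction_bound(self, small_geom):
        params = ModelParams(delta=0.0, eta=0.0)
        assert stable_dt(params, small_geom) == pytest.approx(
            0.5 / (2.02 + 2.00 + 17.0))

    def test_halving_h_quarters_diffusive_bound(self):
        params = ModelParams(delta=50.0, eta=0.0)  # diffusion-dominated
        g1 = _line_geometry(8)
        g2 = BrainGeometry(g1.mask, g1.B0, g1.D, spacing=g1.spacing / 2)
        assert stable_dt(params, g1) == pytest.approx(
            0.5 * g1.spacing**2 / (4 * params.delta))
        assert stable_dt(params, g2) == pytest.approx(
            stable_dt(params, g1) / 4)


class TestStep:
    def test_zero_state_stays_zero(self, small_geom, default_params):
        sh = small_geom.shape
        st = TumorState(np.zeros(sh), np.zeros(sh),
                        small_geom.B0.copy(), np.zeros(sh))
        dt = stable_dt(default_params, small_geom)
        out = step(st, small_geom, default_params, dt)
        assert np.all(out.P == 0) and np.all(out.I == 0)

    def test_unstable_dt_rejected(self, small_geom, seeded_state, default_params):
        dt = stable_dt(default_params, small_geom)
        with pytest.raises(ValueError, match="stability"):
            step(seeded_state, small_geom, default_params, 3 * dt)
        step(seeded_state, small_geom, default_params, 3 * dt,
             override_stability=True)  # no raise

    def test_mass_conserved_without_mitosis(self, small_geom):
        """tau = 0: reaction terms only shuffle mass between compartments."""
        params = ModelParams(tau=0.0, delta=4e-3, eta=1.4e-3)
        dt = stable_dt(params, small_geom)
        st = seed_tumor(small_geom)
        m0 = st.total_mass
        st, _ = advance(st, small_geom, params, dt, 1000)
        assert abs(st.total_mass - m0) / m0 < 1e-8

    def test_exponential_growth_matches_scalar_ode(self, small_geom):
        """Uniform low-density tumour in normoxia grows like the scalar ODE."""
        from scipy.integrate import solve_ivp
        from gliotrial.model_core import reaction_terms

        params = ModelParams(delta=0.0, eta=0.0)
        sh = small_geom.shape
        m = small_geom.mask
        st = TumorState(np.full(sh, 0.05) * m, np.zeros(sh),
                        small_geom.B0.copy(), np.zeros(sh))
        dt = stable_dt(params, small_geom)
        n = 400
        out, _ = advance(st, small_geom, params, dt, n)

        def rhs(t, y):
            s = TumorState(np.array([[y[0]]]), np.array([[y[1]]]),
                           np.array([[y[2]]]), np.array([[y[3]]]))
            return [v[0, 0] for v in reaction_terms(s, params)]

        sol = solve_ivp(rhs, (0, dt * n), [0.05, 0.0, 1.0, 0.0],
                        rtol=1e-10, atol=1e-12)
        # forward Euler is first-order; allow its discretisation bias
        r, c = np.argwhere(m)[0]
        assert out.P[r, c] == pytest.approx(sol.y[0, -1], rel=1e-2)

    def test_kernel_matches_numpy_reference(self, small_geom):
        """The fused kernel reproduces the composed NumPy operators."""
        rng = np.random.default_rng(1)
        sh = small_geom.shape
        m = small_geom.mask
        st = TumorState(rng.uniform(0, 1.5, sh) * m, rng.uniform(0, 1, sh) * m,
                        rng.uniform(0.05, 1, sh) * m, rng.uniform(0, 2, sh) * m)
        params = ModelParams(delta=4e-3, eta=1.4e-3)
        dt = stable_dt(params, small_geom)
        a = st.copy()
        for _ in range(20):
            a = step(a, small_geom, params, dt)
        b, _ = advance(st, small_geom, params, dt, 20)
        for x, y in [(a.P, b.P), (a.I, b.I), (a.B, b.B), (a.N, b.N)]:
            assert np.max(np.abs(x - y)) < 1e-12

    def test_kernel_background_bookkeeping_matches_numpy(self, small_geom):
        """Localized seed: the bounding-box/background path is exact."""
        params = ModelParams(delta=4e-3, eta=1.4e-3)
        dt = stable_dt(params, small_geom)
        a = seed_tumor(small_geom)
        for _ in range(300):
            a = step(a, small_geom, params, dt)
        b, _ = advance(seed_tumor(small_geom), small_geom, params, dt, 300)
        for x, y in [(a.P, b.P), (a.I, b.I), (a.B, b.B), (a.N, b.N)]:
            assert np.max(np.abs(x - y)) < 1e-12

    def test_positivity_over_long_run(self, small_geom, default_params):
        dt = stable_dt(default_params, small_geom)
        st, _ = advance(seed_tumor(small_geom), small_geom,
                        default_params, dt, 3000)
        for f in (st.P, st.I, st.B, st.N):
            assert f.min() >= 0.0


class TestSimulate:
    def test_no_tumour_gives_constant_summaries(self, small_geom, default_params):
        sh = small_geom.shape
        init = TumorState(np.zeros(sh), np.zeros(sh),
                          small_geom.B0.copy(), np.zeros(sh))
        traj = simulate(small_geom, init, default_params, max_time=120.0)
        assert all(s.pct_flair == 0 and s.pct_necrosis == 0
                   for s in traj.summaries)
        assert traj.censored

    def test_determinism(self, small_geom, default_params):
        t1 = simulate(small_geom, seed_tumor(small_geom), default_params,
                      max_time=240.0)
        t2 = simulate(small_geom, seed_tumor(small_geom), default_params,
                      max_time=240.0)
        assert np.array_equal(t1.final_state.P, t2.final_state.P)
        assert np.array_equal(t1.final_state.B, t2.final_state.B)

    def test_schedule_event_fires_once_and_modifies_params(self, small_geom,
                                                           default_params):
        fired = []
        sched = Schedule([(24.0, lambda p: (fired.append(1), p.replace(sigma=0.0))[1])])
        traj = simulate(small_geom, seed_tumor(small_geom), default_params,
                        schedule=sched, max_time=120.0)
        assert fired == [1]
        assert traj.event_times == [24.0]

    def test_stop_predicate_ends_run(self, small_geom, default_params):
        traj = simulate(small_geom, seed_tumor(small_geom), default_params,
                        stop=lambda s: s.t >= 48.0, max_time=480.0)
        assert not traj.censored
        assert traj.summaries[-1].t == pytest.approx(48.0)
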