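"""Time stepping: stability, conservation, determinism, ODE agreement."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cdc42polar import model
from cdc42polar.integrator import Simulation, run, stability_check
from cdc42polar.model import FieldState
from cdc42polar.params import ModelParams

REACTION_FREE = dict(
    k0p=0, k1n=0, k2n=0, k3n=0, k8n=0, k4n=0, k5n=0, k6n=0, k7n=0,
    jDp=0, rT=0, rD=0, rGAPI=0, rGAPIIfast=0, rGAPIIslow=0, rnoise=0,
    noise_mode="off",
)


def seeded_state(mesh, p, rng):
    n = mesh.n_nodes
    F = rng.random((n, 5)) * np.array([80.0, 40.0, 10.0, 5.0, 5.0])
    state = FieldState(F, np.zeros(n), p.Ectot, 0.0)
    model.refresh_gef(state, p, mesh)
    return state


class TestStabilityCheck:
    def test_zero_diffusivity_always_stable(self, default_mesh):
        p = ModelParams(DD=0, DT=0, DGAPI=0, DGAPIIfast=0, DGAPIIslow=0, dt=10.0)
        rep = stability_check(p, default_mesh)
        assert rep.stable and np.isinf(rep.dt_max)

    def test_reference_step_is_stable_with_margin(self, default_mesh, table1):
        rep = stability_check(table1, default_mesh)
        assert rep.stable
        assert rep.dt_max > 2 * table1.dt

    def test_oversized_step_rejected(self, default_mesh):
        p = ModelParams(dt=10.0)
        assert not stability_check(p, default_mesh).stable
        with pytest.raises(ValueError, match="stability"):
            Simulation(p, mesh=default_mesh)


class TestPureDiffusion:
    def test_mass_conserved_and_contracting(self, default_mesh, rng):
        p = ModelParams(**REACTION_FREE)
        sim = Simulation(p, mesh=default_mesh, rng=rng,
                         initial=seeded_state(default_mesh, p, rng))
        a = default_mesh.areas
        mass0 = a @ sim.state.fields
        l2_prev = (a @ sim.state.fields**2)
        for k in range(1000):
            sim.step()
            if k % 200 == 0:
                l2 = a @ sim.state.fields**2
                assert np.all(l2 <= l2_prev * (1 + 1e-12))
                l2_prev = l2
        mass1 = a @ sim.state.fields
        assert np.allclose(mass1, mass0, rtol=1e-10)

    def test_spike_relaxes_to_uniform(self, default_mesh):
        p = ModelParams(**REACTION_FREE)
        n = default_mesh.n_nodes
        F = np.zeros((n, 5))
        F[0, 0] = 1.0 / default_mesh.areas[0]  # one-molecule spike at a pole
        state = FieldState(F, np.zeros(n), p.Ectot, 0.0)
        model.refresh_gef(state, p, default_mesh)
        sim = Simulation(p, mesh=default_mesh, initial=state)
        w = default_mesh.areas / default_mesh.total_area
        var_prev = np.inf
        for _ in range(40):
            for _ in range(500):
                sim.step()
            cd = sim.state.CD  # fastest-diffusing species
            var = float(w @ (cd - w @ cd) ** 2)
            assert var < var_prev
            var_prev = var
        mean = 1.0 / default_mesh.total_area
        assert sim.state.CD == pytest.approx(mean, rel=0.05)


class TestStepAgainstScalarODE:
    """Uniform fields make every node an uncoupled reactor (no diffusion)."""

    def scalar_rhs(self, p, area):
        V = p.volume

        def rhs(t, y):
            cd, ct, gi, gf, gs = y
            w = (p.k1p * ct + p.k2p * ct * ct) / V
            ec = p.Ectot / (1 + w * area)
            act = p.k0p * w * ec * cd  # s=0 bias at the pole is exp(0)=1
            hyd = (p.k1n + p.k2n * gi + p.k3n * gf + p.k8n * gs) * ct
            return [
                p.jDp + hyd - act - p.rD * cd,
                act - hyd - p.rT * ct,
                p.k4n * ct**2 / (p.ksat**2 + ct**2) - p.rGAPI * gi,
                p.k5n * ct - p.k6n * gf + p.k7n * gs * ct - p.rGAPIIfast * gf,
                p.k6n * gf - p.k7n * gs * ct - p.rGAPIIslow * gs,
            ]

        return rhs

    @pytest.fixture()
    def uniform_setup(self, default_mesh):
        p = ModelParams(noise_mode="off", lam=float("inf"))
        n = default_mesh.n_nodes
        y0 = np.array([80.0, 30.0, 5.0, 1.0, 1.0])
        F = np.tile(y0, (n, 1))
        state = FieldState(F, np.zeros(n), p.Ectot, 0.0)
        model.refresh_gef(state, p, default_mesh)
        return p, state, y0

    def test_reaction_kinetics_match_high_accuracy_ode(
        self, default_mesh, uniform_setup
    ):
        """Integrating the package RHS with a tight RK solver reproduces an
        independently coded scalar ODE to 1e-6 relative over 100 s."""
        p, state, y0 = uniform_setup

        def package_rhs(t, y):
            st = state.copy()
            st.fields[:] = y
            model.refresh_gef(st, p, default_mesh)
            return model.reaction_rates(st, p, default_mesh)[0]

        sol_pkg = solve_ivp(package_rhs, (0, 100), y0, rtol=1e-10, atol=1e-12)
        oracle = self.scalar_rhs(p, default_mesh.total_area)
        sol_ref = solve_ivp(oracle, (0, 100), y0, rtol=1e-10, atol=1e-12)
        assert sol_pkg.y[:, -1] == pytest.approx(sol_ref.y[:, -1], rel=1e-6)

    def test_euler_converges_to_ode_solution(self, default_mesh, uniform_setup):
        p, state, y0 = uniform_setup
        sim = Simulation(p, mesh=default_mesh, initial=state)
        for _ in range(int(100 / p.dt)):
            sim.step()
        oracle = self.scalar_rhs(p, default_mesh.total_area)
        ref = solve_ivp(oracle, (0, 100), y0, rtol=1e-10, atol=1e-12).y[:, -1]
        # forward Euler at dt=0.01 s: first-order accurate
        assert sim.state.fields[0] == pytest.approx(ref, rel=2e-3)
        # uniform initial data stays uniform: diffusion adds nothing
        assert np.ptp(sim.state.fields, axis=0).max() < 1e-8


class TestRun:
    def test_zero_duration_returns_initial_state_only(self, default_mesh, table1):
        sim = Simulation(table1, mesh=default_mesh)
        traj = sim.run(duration=0.0)
        assert len(traj.times) == 1
        assert traj.times[0] == 0.0

    def test_short_duration_warns(self, default_mesh, table1):
        sim = Simulation(table1, mesh=default_mesh)
        with pytest.warns(UserWarning, match="unreliable"):
            sim.run(duration=10.0)

    def test_identical_seeds_identical_trajectories(self, default_mesh):
        p = ModelParams(seed=11)
        a = Simulation(p, mesh=default_mesh).run(duration=120)
        b = Simulation(p, mesh=default_mesh).run(duration=120)
        assert np.array_equal(a.tip1, b.tip1)
        assert np.array_equal(a.masses, b.masses)

    def test_gef_conservation_along_trajectory(self, default_mesh, table1):
        traj = Simulation(table1, mesh=default_mesh).run(duration=150)
        assert traj.gef_err < 1e-12

    def test_trace_csv_roundtrip(self, default_mesh, table1, tmp_path):
        traj = Simulation(table1, mesh=default_mesh).run(duration=120)
        path = tmp_path / "traces.csv"
        traj.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns[:5]) == ["time_s", "tip1_CT", "tip2_CT", "mean_CT", "Ec"]
        assert len(df) == len(traj.times)

    def test_reaction_blowup_aborts_with_diagnostic(self, default_mesh):
        # dissociation far above what dt=0.01 can integrate: CD goes negative
        p = ModelParams(rD=250.0, noise_mode="off")
        sim = Simulation(p, mesh=default_mesh)
        with pytest.raises(RuntimeError, match="CD"):
            for _ in range(10):
                sim.step()

    def test_time_step_halving_converges(self, default_mesh):
        """Halving dt changes the 200-s tip trace by well under 1%."""
        base = dict(ksat=900.0, Ectot=700.0, noise_mode="off", seed=4)
        tips = []
        for dt in (0.01, 0.005):
            p = ModelParams(dt=dt, **base)
            sim = Simulation(p, mesh=default_mesh)
            sim.run(duration=200)
            tips.append(sim.tip_values())
        t1, t2 = np.asarray(tips)
        assert np.all(np.abs(t1 - t2) / np.abs(t2) < 0.01)
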