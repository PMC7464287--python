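"""Explicit time stepping of the coupled diffusion-reaction system.

The five dynamic fields advance by forward Euler with the reference step of
0.01 s: within one step the diffusive flux and the local reaction terms are
added, stochastic activation events are applied, and the quasi-static GEF
field is re-equilibrated to the new Cdc42-GTP field.  The scheme is checked
against the explicit-diffusion stability bound at setup.

The hot loop is a fused numba kernel (:mod:`._kernels`); its agreement with
the pure-numpy reaction evaluation in :mod:`.model` is part of the test
suite.  Concentrations a hair below zero (> -1e-9) are roundoff and are
clamped; anything lower aborts with a diagnostic naming the offending field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model
from ._kernels import euler_step
from .geometry import SurfaceMesh, build_mesh
from .model import FIELD_NAMES, FieldState
from .params import ModelParams

__all__ = [
    "Simulation",
    "Trajectory",
    "Snapshot",
    "StabilityReport",
    "stability_check",
    "step",
    "run",
]

#: arc-length radius of the tip regions used for the recorded tip traces (μm)
DEFAULT_S_TIP = 0.5


@dataclass(frozen=True)
class StabilityReport:
    """Explicit-diffusion stability assessment for a (params, mesh) pair."""

    dt: float
    dt_max: float  # min_i A_i / (D_max · Σ_j w_ij), infinite if D_max = 0
    stable: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        verdict = "stable" if self.stable else "UNSTABLE"
        return f"dt={self.dt} s vs bound {self.dt_max:.4g} s: {verdict}"


def stability_check(p: ModelParams, mesh: SurfaceMesh) -> StabilityReport:
    """Largest stable time step for the fastest-diffusing species."""
    dmax = p.max_diffusivity
    if dmax == 0.0:
        dt_max = np.inf
    else:
        dt_max = float((mesh.areas / (dmax * mesh.wdeg)).min())
    return StabilityReport(dt=p.dt, dt_max=dt_max, stable=p.dt <= dt_max)


@dataclass
class Snapshot:
    """Full per-node field record at one instant."""

    t: float
    fields: np.ndarray  # (N, 5) in FIELD_NAMES order
    CGEF: np.ndarray
    Ec: float

    def __getitem__(self, name: str) -> np.ndarray:
        if name == "CGEF":
            return self.CGEF
        if name == "CGAPII":  # total side GAP, reported as fast + slow
            return self.fields[:, 3] + self.fields[:, 4]
        return self.fields[:, FIELD_NAMES.index(name)]


@dataclass
class Trajectory:
    """Sampled observables of one run.

    ``tip1``/``tip2`` are area-weighted mean Cdc42-GTP over the two tip
    regions (s < 0.5 μm, split by hemisphere); ``mean_ct`` is the
    surface-average Cdc42-GTP; ``masses`` holds the area-integrated total of
    each dynamic field; ``gef_err`` is the largest relative violation of GEF
    conservation seen at the samples.
    """

    times: np.ndarray
    tip1: np.ndarray
    tip2: np.ndarray
    mean_ct: np.ndarray
    Ec: np.ndarray
    masses: np.ndarray  # (n_samples, 5)
    params: ModelParams
    mesh: SurfaceMesh
    snapshots: list[Snapshot] = field(default_factory=list)
    gef_err: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.times,
                "tip1_CT": self.tip1,
                "tip2_CT": self.tip2,
                "mean_CT": self.mean_ct,
                "Ec": self.Ec,
            }
        )
        for k, name in enumerate(FIELD_NAMES):
            df[f"mass_{name}"] = self.masses[:, k]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class Simulation:
    """Stateful integrator bound to one parameter set and mesh.

    Building the mesh, the RNG and the initial state from ``params`` makes a
    run a pure function of (params, seed): two simulations constructed from
    equal parameters produce identical trajectories.
    """

    def __init__(
        self,
        params: ModelParams,
        mesh: SurfaceMesh | None = None,
        rng: np.random.Generator | None = None,
        initial: FieldState | None = None,
    ) -> None:
        self.p = params
        self.mesh = mesh if mesh is not None else build_mesh(params.geometry, seed=params.seed)
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        report = stability_check(params, self.mesh)
        if not report.stable:
            raise ValueError(
                f"time step dt={params.dt} s exceeds the explicit-diffusion "
                f"stability bound {report.dt_max:.4g} s on this mesh"
            )
        self.stability = report
        self.bias = model.activation_bias(params, self.mesh)
        self.state = initial.copy() if initial is not None else model.initial_state(
            params, self.mesh, self.rng
        )
        self._buf = np.empty_like(self.state.fields)
        self._wbuf = np.empty_like(self.state.gef_w)
        self._inv_area = 1.0 / self.mesh.areas
        self._csr = (self.mesh.lap.indptr, self.mesh.lap.indices, self.mesh.lap.data)
        # tip-trace regions: near-pole caps split by hemisphere
        s, z = self.mesh.s, self.mesh.nodes[:, 2]
        self._tip_masks = []
        for sel in (z < 0, z > 0):
            m = (s < DEFAULT_S_TIP) & sel
            w = self.mesh.areas[m]
            self._tip_masks.append((np.flatnonzero(m), w / w.sum()))

    def tip_values(self) -> tuple[float, float]:
        """Area-weighted mean Cdc42-GTP over the two tip regions."""
        ct = self.state.CT
        (i1, w1), (i2, w2) = self._tip_masks
        return float(ct[i1] @ w1), float(ct[i2] @ w2)

    def step(self) -> FieldState:
        """One forward-Euler step: diffusion + reactions, noise, GEF refresh."""
        p, st, mesh = self.p, self.state, self.mesh
        indptr, indices, data = self._csr
        fmin, S, mass_cd = euler_step(
            indptr, indices, data,
            self._inv_area, mesh.areas, self.bias,
            st.fields, self._buf, st.gef_w, self._wbuf, st.Ec,
            p.dt,
            p.DD, p.DT, p.DGAPI, p.DGAPIIfast, p.DGAPIIslow,
            p.k1n, p.k2n, p.k3n, p.k8n, p.k4n, p.k5n, p.k6n, p.k7n,
            p.ksat**p.h, p.h,
            p.k0p, p.k1p, p.k2p,
            p.jDp, p.rT, p.rD, p.rGAPI, p.rGAPIIfast, p.rGAPIIslow,
            p.rnoise if p.noise_mode in ("deterministic", "langevin") else 0.0,
            1.0 / p.volume,
        )
        if fmin < model.NEGATIVE_TOL:
            pre = st.fields + p.dt * (
                model.reaction_rates(st, p, mesh, bias=self.bias)
                + (mesh.lap @ st.fields)
                * self._inv_area[:, None]
                * np.array([p.DD, p.DT, p.DGAPI, p.DGAPIIfast, p.DGAPIIslow])
            )
            k = int(np.argmin(pre.min(axis=0)))
            raise RuntimeError(
                f"instability: {FIELD_NAMES[k]} reached {fmin:.3e} "
                f"at t={st.t + p.dt:.2f} s (dt too large for the reactions?)"
            )
        st.fields, self._buf = self._buf, st.fields
        st.gef_w, self._wbuf = self._wbuf, st.gef_w
        if p.rnoise > 0.0:
            if p.noise_mode == "stochastic":
                if self._apply_noise(mass_cd):
                    # events changed Cdc42-GTP at a few nodes: refresh the
                    # recruitment integral
                    S = float(np.dot(mesh.areas, st.gef_w))
            elif p.noise_mode == "langevin":
                model.apply_langevin_noise(st, p, mesh, p.dt, self.rng)
                ct = st.fields[:, 1]
                st.gef_w = (p.k1p * ct + p.k2p * ct * ct) / p.volume
                S = float(np.dot(mesh.areas, st.gef_w))
        st.Ec = p.Ectot / (1.0 + S)
        st.t += p.dt
        return st

    def _apply_noise(self, mass_cd: float) -> int:
        """Poisson activation events; returns the number applied."""
        p, st, mesh = self.p, self.state, self.mesh
        total = p.rnoise * p.dt * mass_cd
        if total <= 0.0:
            return 0
        n_events = int(self.rng.poisson(total))
        if n_events == 0:
            return 0
        F = st.fields
        rates = F[:, 0] * mesh.areas
        nodes = self.rng.choice(mesh.n_nodes, size=n_events, p=rates / rates.sum())
        nodes, counts = np.unique(nodes, return_counts=True)
        moles = np.minimum(counts.astype(float), rates[nodes])
        dc = moles / mesh.areas[nodes]
        F[nodes, 0] = np.maximum(F[nodes, 0] - dc, 0.0)  # guard cap roundoff
        F[nodes, 1] += dc
        ct = F[nodes, 1]
        st.gef_w[nodes] = (p.k1p * ct + p.k2p * ct * ct) / p.volume
        return n_events

    def run(
        self,
        duration: float | None = None,
        sample_every: float = 1.0,
        snapshot_every: float | None = None,
        sample_hook=None,
    ) -> Trajectory:
        """Integrate for ``duration`` seconds, recording tip traces.

        ``sample_hook(sim)`` (if given) is called at every sample point and
        may return True to stop the run early.
        """
        p = self.p
        duration = p.duration if duration is None else duration
        if 0 < duration < 100:
            warnings.warn(
                f"duration {duration} s is shorter than 100 s; "
                "state classification on such traces is unreliable",
                stacklevel=2,
            )
        n_steps = int(round(duration / p.dt))
        stride = max(int(round(sample_every / p.dt)), 1)
        snap_stride = None
        if snapshot_every is not None:
            snap_stride = max(int(round(snapshot_every / p.dt)), 1)
        rec: dict[str, list] = {k: [] for k in ("t", "t1", "t2", "mc", "ec", "mass")}
        snapshots: list[Snapshot] = []
        gef_err = 0.0
        mean_w = self.mesh.areas / self.mesh.total_area

        def sample() -> bool:
            t1, t2 = self.tip_values()
            st = self.state
            rec["t"].append(st.t)
            rec["t1"].append(t1)
            rec["t2"].append(t2)
            rec["mc"].append(float(st.CT @ mean_w))
            rec["ec"].append(st.Ec)
            rec["mass"].append(self.mesh.areas @ st.fields)
            nonlocal gef_err
            gef_err = max(
                gef_err,
                abs(st.Ec + self.mesh.integrate(st.CGEF) - self.p.Ectot)
                / self.p.Ectot,
            )
            return bool(sample_hook(self)) if sample_hook is not None else False

        stop = sample()
        if snap_stride is not None:
            snapshots.append(self._snapshot())
        for i in range(1, n_steps + 1):
            if stop:
                break
            self.step()
            if i % stride == 0 or i == n_steps:
                stop = sample()
            if snap_stride is not None and i % snap_stride == 0:
                snapshots.append(self._snapshot())
        return Trajectory(
            times=np.asarray(rec["t"]),
            tip1=np.asarray(rec["t1"]),
            tip2=np.asarray(rec["t2"]),
            mean_ct=np.asarray(rec["mc"]),
            Ec=np.asarray(rec["ec"]),
            masses=np.asarray(rec["mass"]),
            params=p,
            mesh=self.mesh,
            snapshots=snapshots,
            gef_err=gef_err,
        )

    def _snapshot(self) -> Snapshot:
        st = self.state
        return Snapshot(t=st.t, fields=st.fields.copy(), CGEF=st.CGEF.copy(), Ec=st.Ec)


def step(
    state: FieldState,
    p: ModelParams,
    mesh: SurfaceMesh,
    rng: np.random.Generator,
) -> FieldState:
    """Functional single-step interface (see :meth:`Simulation.step`)."""
    sim = Simulation(p, mesh=mesh, rng=rng, initial=state)
    return sim.step()


def run(
    p: ModelParams,
    duration: float | None = None,
    sample_every: float = 1.0,
    snapshot_every: float | None = None,
) -> Trajectory:
    """Build mesh and initial state from ``p``, integrate, return trajectory."""
    sim = Simulation(p)
    return sim.run(
        duration=duration, sample_every=sample_every, snapshot_every=snapshot_every
    )
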