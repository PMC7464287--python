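"""Experiment drivers: single runs, phase scans, length series, mutants.

Every driver is a pure function of (parameters, seed): given the same
configuration it reproduces labels and metrics exactly.  Drivers return
both the raw trajectory objects and compact records (dicts / DataFrames)
ready for serialization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis
from .analysis import ClassifierConfig, StateLabel, classify_state, tip_traces
from .geometry import CellGeometry
from .integrator import Simulation, Snapshot, Trajectory
from .params import ModelParams

__all__ = [
    "RunResult",
    "ScanSpec",
    "ScanResult",
    "run_single",
    "run_scan",
    "neto_series",
    "mutant_run",
    "peak_profile_run",
    "MUTANT_SCENARIOS",
]

#: named parameter overrides of the perturbation scenarios
MUTANT_SCENARIOS: dict[str, dict] = {
    # side-GAP recruitment halved, as in cells lacking one side GAP
    "gapII_half": {"k5n": 0.015},
    # side-GAP system removed entirely
    "gapII_off": {"k5n": 0.0},
    # no tip bias; stronger positive feedback restores symmetry breaking
    "unbiased": {"lam": float("inf"), "k0p": 0.01},
    # unbiased and without the side GAP: travelling-wave regime
    "unbiased_gapII_off": {"lam": float("inf"), "k0p": 0.01, "k5n": 0.0},
}


@dataclass
class RunResult:
    """One simulation plus its classification and summary metrics."""

    params: ModelParams
    trajectory: Trajectory
    state: StateLabel

    def record(self) -> dict:
        """Flat JSON-ready provenance record."""
        rec = {
            "seed": self.params.seed,
            "params_digest": self.params.digest(),
            "label": self.state.label,
            "asymmetry": self.state.asymmetry,
            "period_s": self.state.period,
            "modulation": self.state.modulation,
            "duration_s": float(self.trajectory.times[-1]),
            "gef_conservation_err": self.trajectory.gef_err,
        }
        return rec


def run_single(
    p: ModelParams,
    duration: float | None = None,
    snapshot_every: float | None = None,
    classifier: ClassifierConfig = ClassifierConfig(),
) -> RunResult:
    """Integrate one parameter set and classify the outcome.

    In the unbiased-activation regime (``lam`` infinite) the tip traces are
    uninformative, so the label comes from patch tracking over snapshots
    (recorded every 25 s unless requested otherwise).
    """
    unbiased = np.isinf(p.lam)
    if unbiased and snapshot_every is None:
        snapshot_every = 25.0
    sim = Simulation(p)
    traj = sim.run(duration=duration, snapshot_every=snapshot_every)
    if unbiased:
        track = analysis.patch_tracking(traj.snapshots, sim.mesh)
        label = track.label if track.label in ("WAVE", "PATCH_DYNAMIC") else "UNPOLARIZED"
        state = StateLabel(label)
    else:
        state = classify_state(tip_traces(traj), config=classifier)
    return RunResult(params=p, trajectory=traj, state=state)


@dataclass
class ScanSpec:
    """Two-axis parameter scan around a base parameter set."""

    axis1: tuple[str, list[float]]
    axis2: tuple[str, list[float]]
    base: ModelParams
    replicates: int = 1
    duration: float = 1200.0

    def __post_init__(self) -> None:
        names = {f.name for f in dataclasses.fields(ModelParams)}
        for name, values in (self.axis1, self.axis2):
            if name not in names:
                raise ValueError(f"unknown scan parameter {name!r}")
            if len(values) == 0:
                raise ValueError(f"empty value list for {name!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class ScanResult:
    """Grid of state labels with per-cell provenance."""

    spec: ScanSpec
    table: pd.DataFrame  # columns: axis1, axis2, replicate, seed, label, ...

    def label_grid(self) -> pd.DataFrame:
        """Majority label per grid cell (ties resolved by first occurrence),
        with a ``coexist`` flag when replicates disagree."""
        n1, _ = self.spec.axis1
        n2, _ = self.spec.axis2

        def majority(g: pd.DataFrame) -> pd.Series:
            counts = g["label"].value_counts()
            return pd.Series(
                {"label": counts.index[0], "coexist": len(counts) > 1}
            )
        cols = self.table.groupby([n1, n2]).apply(majority, include_groups=False)
        return cols.reset_index()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @staticmethod
    def from_csv(path, spec: ScanSpec | None = None) -> "ScanResult":
        return ScanResult(spec=spec, table=pd.read_csv(path))


def run_scan(
    spec: ScanSpec,
    classifier: ClassifierConfig = ClassifierConfig(),
    mesh_cache: dict | None = None,
) -> ScanResult:
    """Run and classify every grid point; failures are recorded, not raised."""
    n1, v1 = spec.axis1
    n2, v2 = spec.axis2
    rows = []
    rng = np.random.default_rng(spec.base.seed)
    for a in v1:
        for b in v2:
            for rep in range(spec.replicates):
                seed = int(rng.integers(0, 2**31 - 1))
                p = spec.base.replace(**{n1: a, n2: b, "seed": seed})
                row = {n1: a, n2: b, "replicate": rep, "seed": seed,
                       "params_digest": p.digest()}
                try:
                    res = _run_cached(p, spec.duration, classifier, mesh_cache)
                    row.update(label=res.state.label,
                               asymmetry=res.state.asymmetry,
                               period_s=res.state.period,
                               modulation=res.state.modulation)
                except Exception as exc:  # per-cell failure: record and go on
                    row.update(label="ERROR", error=str(exc))
                rows.append(row)
    return ScanResult(spec=spec, table=pd.DataFrame(rows))


def _run_cached(p, duration, classifier, mesh_cache):
    if mesh_cache is None:
        return run_single(p, duration=duration, classifier=classifier)
    key = (p.L, p.R, p.target_cell_area)
    if key not in mesh_cache:
        from .geometry import build_mesh

        mesh_cache[key] = build_mesh(p.geometry, seed=p.seed)
    sim = Simulation(p, mesh=mesh_cache[key])
    traj = sim.run(duration=duration)
    state = classify_state(tip_traces(traj), config=classifier)
    return RunResult(params=p, trajectory=traj, state=state)


def neto_series(
    lengths: list[float],
    base: ModelParams | None = None,
    Ectot_ref: float = 300.0,
    L_ref: float = 7.0,
    duration: float = 1200.0,
    classifier: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Cell-length series with the GEF pool scaled in proportion to volume.

    Models growth across the monopolar-to-bipolar (NETO) transition: for
    each length ``L`` the total GEF is ``Ectot_ref · V(L)/V(L_ref)`` and the
    terminal state is classified.  The reference anchoring is 300 GEF
    molecules at L = 7 μm.
    """
    if base is None:
        base = ModelParams(ksat=650.0)
    v_ref = CellGeometry(L=L_ref, R=base.R).volume
    rows = []
    for L in lengths:
        vol = CellGeometry(L=L, R=base.R).volume
        ectot = Ectot_ref * vol / v_ref
        p = base.replace(L=L, Ectot=ectot)
        try:
            res = run_single(p, duration=duration, classifier=classifier)
            rows.append({
                "L": L, "Ectot": ectot, "label": res.state.label,
                "period_s": res.state.period, "asymmetry": res.state.asymmetry,
                "seed": p.seed,
            })
        except Exception as exc:
            rows.append({"L": L, "Ectot": ectot, "label": "ERROR", "error": str(exc)})
    return pd.DataFrame(rows)


def mutant_run(
    scenario: str,
    overrides: dict | None = None,
    base: ModelParams | None = None,
    duration: float | None = None,
) -> dict:
    """Run one named perturbation scenario and bundle run + analyses.

    Returns a dict with the trajectory, state label, arc-length profiles of
    the final snapshot and (when a Cdc42-GTP gradient exists) the fitted
    exponential decay length.
    """
    if scenario not in MUTANT_SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid: {sorted(MUTANT_SCENARIOS)}"
        )
    base = base if base is not None else ModelParams()
    merged = dict(MUTANT_SCENARIOS[scenario])
    merged.update(overrides or {})
    p = base.replace(**merged)
    res = run_single(p, duration=duration, snapshot_every=25.0)
    sim_mesh = res.trajectory.mesh
    snap = res.trajectory.snapshots[-1] if res.trajectory.snapshots else None
    bundle = {
        "scenario": scenario,
        "params": p,
        "trajectory": res.trajectory,
        "state": res.state,
        "profiles": None,
        "decay_length_um": None,
    }
    if snap is not None:
        profiles = analysis.profile_vs_arclength(snap, sim_mesh)
        bundle["profiles"] = profiles
        try:
            ell, err = analysis.decay_length_fit(profiles["CT"])
            bundle["decay_length_um"] = ell
            bundle["decay_length_err_um"] = err
        except (ValueError, RuntimeError):
            pass
    return bundle


def peak_profile_run(
    p: ModelParams,
    t_min: float = 1000.0,
    delay: float = 20.0,
    max_extra: float = 600.0,
    lookback: float = 31.0,
    min_prominence: float = 0.05,
) -> tuple[Snapshot, Simulation]:
    """Snapshot the fields ``delay`` seconds after a dominant-tip peak.

    The run proceeds to ``t_min``, then watches the tip traces (1-s
    sampling) for a local maximum of the currently dominant tip: the sample
    at the center of a ``lookback``-second window is a peak if it is the
    window maximum and exceeds the window minimum by ``min_prominence``
    relative.  The simulation then advances ``delay`` seconds past the peak
    time and the full state is returned.  Raises if no peak appears within
    ``max_extra`` seconds past ``t_min``.
    """
    sim = Simulation(p)
    sim.run(duration=t_min, sample_every=10.0)
    half = int(lookback) // 2
    buf_t: list[float] = []
    buf: list[tuple[float, float]] = []
    peak_t: list[float] = []

    def hook(s: Simulation) -> bool:
        buf_t.append(s.state.t)
        buf.append(s.tip_values())
        if peak_t:
            return s.state.t >= peak_t[0] + delay
        if len(buf) < int(lookback):
            return False
        win = np.asarray(buf[-int(lookback):])
        for col in (0, 1):
            x = win[:, col]
            v = x[half]
            other = win[half, 1 - col]
            if (
                v == x.max()
                and v > other
                and v - x.min() > min_prominence * v
            ):
                peak_t.append(buf_t[-int(lookback) + half])
                return False
        return False

    traj = sim.run(duration=max_extra + delay, sample_every=1.0, sample_hook=hook)
    if not peak_t:
        raise RuntimeError(
            f"no dominant-tip peak found within {max_extra} s after t={t_min} s"
        )
    del traj
    return sim._snapshot(), sim
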