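"""Reduction of trajectories to the observables of the polarization study.

The central readouts are the two tip traces of Cdc42-GTP, from which runs
are classified into the canonical dynamical states:

``MPS``
    monopolar stable - one dominant tip, stationary.
``BPS``
    bipolar stable - both tips active and equal, stationary.
``BPO``
    bipolar oscillatory - deep anticorrelated switching of tip dominance.
``MPDO``
    monopolar with damped oscillations - anticorrelated oscillations that
    decay towards an asymmetric state (under sustained activation noise the
    decayed state appears as small irregular anticorrelated fluctuations).
``UNPOLARIZED``
    no tip enrichment over the surface mean.
``PATCH_DYNAMIC`` / ``WAVE``
    patch appearance/disappearance at random locations, or a travelling
    activation zone; diagnosed from snapshots (:func:`patch_tracking`), the
    regime of unbiased activation.

Spatial readouts are arc-length concentration profiles measured from the
dominant tip, exponential decay lengths of the Cdc42-GTP profile, and the
tip-to-side enrichment of total Cdc42.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .geometry import SurfaceMesh
from .integrator import DEFAULT_S_TIP, Snapshot, Trajectory

__all__ = [
    "STATE_LABELS",
    "TipTraces",
    "StateLabel",
    "Profile",
    "ClassifierConfig",
    "tip_traces",
    "classify_state",
    "oscillation_period",
    "profile_vs_arclength",
    "decay_length_fit",
    "tip_to_side_ratio",
    "patch_tracking",
]

STATE_LABELS = (
    "UNPOLARIZED",
    "MPS",
    "BPS",
    "MPDO",
    "BPO",
    "PATCH_DYNAMIC",
    "WAVE",
    "INDETERMINATE",
)


@dataclass
class TipTraces:
    """Paired tip time series of Cdc42-GTP (area-weighted tip-region means)."""

    t: np.ndarray
    tip1: np.ndarray
    tip2: np.ndarray
    mean_ct: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.tip1) == len(self.tip2)):
            raise ValueError("tip traces and time axis must have equal length")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0

    def swapped(self) -> "TipTraces":
        return TipTraces(self.t, self.tip2.copy(), self.tip1.copy(), self.mean_ct)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.t, "tip1_CT": self.tip1, "tip2_CT": self.tip2})


@dataclass
class StateLabel:
    """Categorical outcome of a run plus the metrics behind the decision."""

    label: str
    asymmetry: float = np.nan        # time-averaged dominant/lagging tip ratio
    period: float | None = None      # s, only for oscillatory labels
    damping: float | None = None     # per-cycle envelope ratio, if measured
    modulation: float = np.nan       # (max-min)/(max+min) of the deeper trace

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class Profile:
    """Area-weighted mean concentration vs arc-length distance from a tip."""

    s_bins: np.ndarray     # bin centers (μm)
    values: np.ndarray     # mean concentration per bin (1/μm²)
    species: str
    merged_bins: int = 0   # empty bins merged into a neighbor


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the state decision tree (all dimensionless or seconds).

    The published model states no numeric criteria, so these are defined
    operationally: ``asymmetry_ratio`` separates monopolar from bipolar
    time-averaged tip ratios; oscillation requires ``min_peaks`` prominent
    maxima on each trace within the evaluation window plus anticorrelation;
    ``deep_modulation`` separates full dominance switching (bipolar
    oscillations drive each tip close to zero, modulation depth near 1) from
    the shallow residual fluctuations of a damped oscillatory state;
    ``damping_ratio`` is the per-cycle envelope decay below which transient
    oscillations count as damped.
    """

    window: float = 400.0
    asymmetry_ratio: float = 1.5
    min_peaks: int = 3
    peak_prominence: float = 0.10    # fraction of the trace mean
    anticorrelation: float = -0.2
    stationary_drift: float = 0.02   # relative drift of 100-s block means
    deep_modulation: float = 0.70
    damping_ratio: float = 0.7
    unpolarized_enrichment: float = 1.5  # tip mean over surface mean


def tip_traces(
    trajectory: Trajectory,
    mesh: SurfaceMesh | None = None,
    s_tip: float = DEFAULT_S_TIP,
) -> TipTraces:
    """Extract the paired tip traces from a trajectory.

    With the default tip radius the traces recorded during the run are
    returned directly; a different ``s_tip`` requires snapshots to
    recompute the regional averages.
    """
    mesh = mesh if mesh is not None else trajectory.mesh
    if s_tip <= 0:
        raise ValueError("s_tip must be positive")
    if s_tip > mesh.geom.max_tip_distance:
        raise ValueError(
            f"s_tip={s_tip} μm exceeds the half-meridian "
            f"({mesh.geom.max_tip_distance:.3f} μm)"
        )
    if s_tip == DEFAULT_S_TIP:
        return TipTraces(
            trajectory.times, trajectory.tip1, trajectory.tip2, trajectory.mean_ct
        )
    if not trajectory.snapshots:
        raise ValueError(
            "recomputing traces with a non-default s_tip needs snapshots"
        )
    s, z = mesh.s, mesh.nodes[:, 2]
    out = {"t": [], "1": [], "2": []}
    for snap in trajectory.snapshots:
        out["t"].append(snap.t)
        for key, sel in (("1", z < 0), ("2", z > 0)):
            m = (s < s_tip) & sel
            w = mesh.areas[m]
            out[key].append(float(snap["CT"][m] @ (w / w.sum())))
    return TipTraces(np.asarray(out["t"]), np.asarray(out["1"]), np.asarray(out["2"]))


def oscillation_period(
    t: np.ndarray,
    x: np.ndarray,
    transient_cut: float = 0.0,
    peak_prominence: float = 0.30,
) -> float | None:
    """Mean inter-peak interval of prominent maxima after ``transient_cut``.

    Returns None when fewer than 3 peaks are found (no oscillation).  The
    default prominence (30% of the trace mean) deliberately exceeds the
    classifier's oscillation-detection threshold: relaxation oscillations
    ride small ripples on their plateaus that would otherwise double-count
    cycles.
    """
    sel = t >= transient_cut
    ts, xs = t[sel], x[sel]
    if len(xs) < 5:
        return None
    prom = peak_prominence * max(xs.mean(), 1e-12)
    peaks, _ = find_peaks(xs, prominence=prom)
    if len(peaks) < 3:
        return None
    return float(np.diff(ts[peaks]).mean())


def _block_drift(t: np.ndarray, x: np.ndarray, block: float = 100.0) -> float:
    """Relative change between the first and last ``block``-second means."""
    first = x[t <= t[0] + block]
    last = x[t >= t[-1] - block]
    scale = max(abs(x.mean()), 1e-12)
    return abs(last.mean() - first.mean()) / scale


def _modulation_depth(x: np.ndarray) -> float:
    lo, hi = float(x.min()), float(x.max())
    return (hi - lo) / (hi + lo) if hi + lo > 0 else 0.0


def _envelope_ratio(
    t: np.ndarray, x: np.ndarray, prom_frac: float, scale: float | None = None
) -> float | None:
    """Mean ratio of successive peak prominences (per-cycle envelope decay)."""
    prom = prom_frac * max(x.mean() if scale is None else scale, 1e-12)
    peaks, props = find_peaks(x, prominence=prom)
    if len(peaks) < 2:
        return None
    amp = props["prominences"]
    ratios = amp[1:] / amp[:-1]
    return float(np.exp(np.mean(np.log(ratios))))


def classify_state(
    traces: TipTraces,
    window: float | None = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> StateLabel:
    """Decision tree over the paired tip traces.

    The final ``window`` seconds decide stationarity, symmetry and
    oscillation; the earlier part of the trace is consulted to recognise
    damped transient oscillations.  Traces shorter than two windows return
    an explicit INDETERMINATE label rather than a silent default.
    """
    window = config.window if window is None else window
    t, x1, x2 = traces.t, traces.tip1, traces.tip2
    if traces.duration < 2 * window:
        return StateLabel("INDETERMINATE")
    # final window decides stationarity; a longer post-transient span (enough
    # to hold several multi-minute oscillation cycles) decides oscillation
    w = t >= t[-1] - window
    span = t >= t[0] + 0.15 * traces.duration
    tw, a, b = t[w], x1[w], x2[w]
    sa, sb = x1[span], x2[span]
    m1, m2 = float(a.mean()), float(b.mean())
    hi, lo = max(m1, m2), min(m1, m2)
    asym = hi / max(lo, 1e-12)
    # oscillation: enough prominent peaks on both traces, anticorrelated
    pk1, _ = find_peaks(sa, prominence=config.peak_prominence * max(sa.mean(), 1e-12))
    pk2, _ = find_peaks(sb, prominence=config.peak_prominence * max(sb.mean(), 1e-12))
    if sa.std() > 0 and sb.std() > 0:
        corr = float(np.corrcoef(sa, sb)[0, 1])
    else:
        corr = 0.0
    deep = min(_modulation_depth(sa), _modulation_depth(sb))
    # slow relaxation oscillations may fit fewer than min_peaks cycles into
    # the trace; deep, repeated exchanges of tip dominance are still
    # unambiguous switching, counted with a dead band against jitter
    d = sa - sb
    level = 0.5 * (sa.mean() + sb.mean())
    signs = np.sign(d[np.abs(d) > 0.4 * max(level, 1e-12)])
    crossings = int(np.sum(signs[1:] != signs[:-1])) if len(signs) > 1 else 0
    oscillatory = (
        len(pk1) >= config.min_peaks
        and len(pk2) >= config.min_peaks
        and corr < config.anticorrelation
    ) or (
        crossings >= config.min_peaks
        and deep >= config.deep_modulation
        and corr < config.anticorrelation
    )
    period = oscillation_period(t, x1 if m1 >= m2 else x2, t[span][0])
    if oscillatory:
        # anticorrelated oscillations average out over full cycles, so
        # symmetry is judged on the span means
        osc_asym = max(sa.mean(), sb.mean()) / max(min(sa.mean(), sb.mean()), 1e-12)
        if deep >= config.deep_modulation and osc_asym < config.asymmetry_ratio:
            return StateLabel("BPO", asymmetry=osc_asym, period=period, modulation=deep)
        # shallow or asymmetric oscillations: the residual of a damped
        # oscillatory state kept alive by activation noise
        env = _envelope_ratio(t, x1 if m1 >= m2 else x2, config.peak_prominence)
        return StateLabel(
            "MPDO", asymmetry=osc_asym, period=period, damping=env, modulation=deep
        )
    # non-oscillatory: stationary states
    drift = max(_block_drift(tw, a), _block_drift(tw, b))
    if traces.mean_ct is not None:
        mean_ct = float(np.asarray(traces.mean_ct)[w].mean())
        if hi < config.unpolarized_enrichment * mean_ct and mean_ct > 0:
            return StateLabel("UNPOLARIZED", asymmetry=asym)
    if drift > config.stationary_drift:
        # a rare, complete dominance swap is still a monopolar state (the two
        # tips are equivalent); require instantaneous asymmetry most of the time
        ratio = np.maximum(sa, sb) / np.maximum(np.minimum(sa, sb), 1e-12)
        frac_asym = float(np.mean(ratio > config.asymmetry_ratio))
        if frac_asym > 0.8:
            return StateLabel("MPS", asymmetry=asym, modulation=deep)
        return StateLabel("INDETERMINATE", asymmetry=asym, modulation=deep)
    if asym >= config.asymmetry_ratio:
        # asymmetric stationary end state: monopolar; transient anticorrelated
        # oscillations earlier in the trace mark it as the damped-oscillatory
        # relative of MPS
        pre = t < t[-1] - window
        diff = (x1 - x2)[pre]
        env = _envelope_ratio(t[pre], diff - diff.mean(), config.peak_prominence,
                              scale=float(np.abs(diff).mean()))
        if env is not None and env < config.damping_ratio:
            return StateLabel("MPDO", asymmetry=asym, damping=env, modulation=deep)
        return StateLabel("MPS", asymmetry=asym, modulation=deep)
    return StateLabel("BPS", asymmetry=asym, modulation=deep)


def _distance_from_tip(mesh: SurfaceMesh, tip: int) -> np.ndarray:
    """Meridian arc-length distance from the chosen tip (1 or 2) per node."""
    z = mesh.nodes[:, 2]
    on_far_side = (z > 0) if tip == 1 else (z < 0)
    d = mesh.s.copy()
    d[on_far_side] = mesh.geom.meridian_length - mesh.s[on_far_side]
    return d


def dominant_tip(snapshot: Snapshot, mesh: SurfaceMesh, s_tip: float = DEFAULT_S_TIP) -> int:
    """Tip (1 or 2) with the larger tip-region Cdc42-GTP mean."""
    s, z = mesh.s, mesh.nodes[:, 2]
    means = []
    for sel in (z < 0, z > 0):
        m = (s < s_tip) & sel
        w = mesh.areas[m]
        means.append(float(snapshot["CT"][m] @ (w / w.sum())))
    return 1 if means[0] >= means[1] else 2


def profile_vs_arclength(
    snapshot: Snapshot,
    mesh: SurfaceMesh,
    species: str | tuple[str, ...] = ("CD", "CT", "CGAPI", "CGAPII", "CGEF"),
    bin_width: float = 0.25,
    align_to: int | None = None,
) -> dict[str, Profile]:
    """Area-weighted concentration profiles vs distance from the dominant tip.

    ``bin_width`` must not be finer than the mesh spacing (empty bins are
    merged into their left neighbor and counted).  The side-GAP profile is
    reported as the sum of its fast and slow forms under the key
    ``"CGAPII"``.
    """
    mean_spacing = float(np.sqrt(mesh.areas.mean()))
    if bin_width < mean_spacing:
        raise ValueError(
            f"bin_width {bin_width} μm is below the mesh spacing "
            f"(~{mean_spacing:.3f} μm); bins would be empty"
        )
    tip = align_to if align_to is not None else dominant_tip(snapshot, mesh)
    d = _distance_from_tip(mesh, tip)
    edges = np.arange(0.0, mesh.geom.meridian_length + bin_width, bin_width)
    idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    if isinstance(species, str):
        species = (species,)
    out: dict[str, Profile] = {}
    area_tot = np.bincount(idx, weights=mesh.areas, minlength=len(edges) - 1)
    for name in species:
        f = snapshot[name]
        num = np.bincount(idx, weights=mesh.areas * f, minlength=len(edges) - 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = area_tot > 0
        merged = int((~keep).sum())
        vals = np.where(area_tot > 0, num / np.maximum(area_tot, 1e-300), np.nan)
        # merge empty bins into the previous occupied one
        vals = pd.Series(vals).ffill().to_numpy()
        out[name] = Profile(
            s_bins=centers, values=vals, species=name, merged_bins=merged
        )
    return out


def decay_length_fit(
    profile: Profile,
    fit_range: tuple[float, float] = (0.0, 2.0),
) -> tuple[float, float]:
    """Exponential decay length of a profile near the tip.

    Least-squares fit of ``c(s) = c0 · exp(-s/ℓ)`` over ``fit_range``;
    returns ``(ℓ, stderr)`` in μm.  Non-positive bins inside the range are
    dropped before fitting.
    """
    lo, hi = fit_range
    sel = (profile.s_bins >= lo) & (profile.s_bins <= hi)
    s, c = profile.s_bins[sel], profile.values[sel]
    pos = c > 0
    s, c = s[pos], c[pos]
    if len(s) < 5:
        raise ValueError(
            f"need at least 5 positive bins in {fit_range}, got {len(s)}"
        )
    # log-linear start, refined by nonlinear least squares on the raw values
    slope, intercept = np.polyfit(s, np.log(c), 1)
    ell0 = -1.0 / slope if slope < 0 else 1.0
    popt, pcov = curve_fit(
        lambda x, c0, ell: c0 * np.exp(-x / ell),
        s,
        c,
        p0=(float(np.exp(intercept)), float(abs(ell0))),
        maxfev=10000,
    )
    return float(popt[1]), float(np.sqrt(pcov[1, 1]))


def tip_to_side_ratio(
    snapshot: Snapshot,
    mesh: SurfaceMesh,
    s_tip: float = DEFAULT_S_TIP,
    side_halfwidth: float = 1.0,
) -> float:
    """Total-Cdc42 (GDP+GTP) enrichment of the active tip over mid-cell.

    Area-weighted mean of ``CD + CT`` within ``s_tip`` of the dominant tip,
    divided by the mean over the mid-cell band (within ``side_halfwidth`` of
    the meridian midpoint).  The two regions must not overlap.
    """
    smax = mesh.geom.max_tip_distance
    if s_tip >= smax - side_halfwidth:
        raise ValueError("tip region and mid-cell side band overlap")
    tip = dominant_tip(snapshot, mesh, s_tip)
    d = _distance_from_tip(mesh, tip)
    total = snapshot["CD"] + snapshot["CT"]
    tip_sel = d < s_tip
    side_sel = np.abs(mesh.s - smax) < side_halfwidth
    wt, ws = mesh.areas[tip_sel], mesh.areas[side_sel]
    return float((total[tip_sel] @ wt / wt.sum()) / (total[side_sel] @ ws / ws.sum()))


@dataclass
class PatchTrack:
    """Centroid path of the activation patch across snapshots."""

    times: np.ndarray
    centroids: np.ndarray        # (n, 3), on-surface positions (μm)
    speeds: np.ndarray           # (n-1,) centroid speed between snapshots
    patch_diameter: float        # μm, from the top-decile patch area
    n_jumps: int                 # appearances at distant locations
    directedness: float          # |net displacement| / path length
    label: str                   # WAVE, PATCH_DYNAMIC, or STATIONARY_PATCH

    def __post_init__(self) -> None:
        assert self.label in ("WAVE", "PATCH_DYNAMIC", "STATIONARY_PATCH", "NO_PATCH")


def patch_tracking(
    snapshots: list[Snapshot],
    mesh: SurfaceMesh,
    decile: float = 0.9,
    min_contrast: float = 2.0,
) -> PatchTrack:
    """Track the area-weighted centroid of the top-decile Cdc42-GTP nodes.

    Persistent directed motion (net displacement above the patch diameter
    with high path directedness) is a travelling wave; repeated centroid
    jumps larger than the patch diameter without directed motion mark patch
    appearance/disappearance dynamics.  Snapshots without contrast
    (max < ``min_contrast`` × mean) carry no patch.
    """
    times, cents = [], []
    areas = mesh.areas
    patch_area = 0.0
    n_with_patch = 0
    for snap in snapshots:
        ct = snap["CT"]
        mean = float(np.average(ct, weights=areas))
        if ct.max() < min_contrast * max(mean, 1e-12):
            continue
        thr = np.quantile(ct, decile)
        sel = ct >= thr
        w = areas[sel] * ct[sel]
        c = (mesh.nodes[sel] * w[:, None]).sum(axis=0) / w.sum()
        times.append(snap.t)
        cents.append(c)
        patch_area += float(areas[sel].sum())
        n_with_patch += 1
    if n_with_patch < 2:
        return PatchTrack(
            np.asarray(times), np.zeros((0, 3)), np.zeros(0), 0.0, 0, 0.0, "NO_PATCH"
        )
    cents = np.asarray(cents)
    times_a = np.asarray(times)
    patch_area /= n_with_patch
    diameter = 2.0 * np.sqrt(patch_area / np.pi)
    steps = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    dt_steps = np.diff(times_a)
    speeds = steps / np.maximum(dt_steps, 1e-12)
    path = float(steps.sum())
    net = float(np.linalg.norm(cents[-1] - cents[0]))
    directedness = net / path if path > 0 else 0.0
    n_jumps = int((steps > diameter).sum())
    # a wave travelling on the closed surface returns near its start, so net
    # displacement cannot distinguish it from hopping patches; steady motion
    # (low step-length dispersion) can: waves advance a similar distance
    # every interval, while appearing/disappearing patches alternate
    # stationary episodes with jumps
    step_cv = float(steps.std() / steps.mean()) if steps.mean() > 0 else 0.0
    if path <= diameter:
        label = "STATIONARY_PATCH"
    elif step_cv < 0.6 and path > 2 * diameter:
        label = "WAVE"
    else:
        label = "PATCH_DYNAMIC"
    return PatchTrack(times_a, cents, speeds, diameter, n_jumps, directedness, label)
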