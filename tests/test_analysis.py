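"""Trace classification, periods, profiles, decay fits, patch tracking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdc42polar import analysis
from cdc42polar.analysis import (
    Profile,
    TipTraces,
    classify_state,
    decay_length_fit,
    oscillation_period,
    patch_tracking,
    profile_vs_arclength,
    tip_to_side_ratio,
    tip_traces,
)
from cdc42polar.integrator import Snapshot


def traces(t, x1, x2, mean_ct=None):
    return TipTraces(np.asarray(t, float), np.asarray(x1, float),
                     np.asarray(x2, float), mean_ct)


T = np.arange(0.0, 1201.0)


def snapshot_from(mesh, CD=0.0, CT=0.0, t=0.0):
    n = mesh.n_nodes
    F = np.zeros((n, 5))
    F[:, 0] = CD
    F[:, 1] = CT
    return Snapshot(t=t, fields=F, CGEF=np.zeros(n), Ec=0.0)


class TestClassifier:
    def test_constant_equal_traces_are_bipolar_stable(self):
        out = classify_state(traces(T, np.full_like(T, 100.0), np.full_like(T, 100.0)))
        assert out.label == "BPS"
        assert out.period is None

    def test_constant_asymmetric_traces_are_monopolar_stable(self):
        out = classify_state(traces(T, np.full_like(T, 150.0), np.full_like(T, 20.0)))
        assert out.label == "MPS"
        assert out.asymmetry > 5

    def test_deep_anticorrelated_oscillation_is_bpo(self):
        x = 50 + 48 * np.sin(2 * np.pi * T / 300.0)
        out = classify_state(traces(T, x, 100 - x))
        assert out.label == "BPO"
        assert out.period == pytest.approx(300.0, abs=5.0)

    def test_damped_oscillation_to_asymmetric_state_is_mpdo(self):
        env = np.exp(-T / 200.0)
        x1 = 60 + 40 * env * np.cos(2 * np.pi * T / 250.0) - 30 * (1 - env)
        x2 = 60 - 40 * env * np.cos(2 * np.pi * T / 250.0) + 30 * (1 - env)
        # end state: x1 -> 30, x2 -> 90 (asymmetric), oscillations decayed
        out = classify_state(traces(T, x2, x1))
        assert out.label == "MPDO"

    def test_shallow_sustained_anticorrelated_fluctuation_is_mpdo(self):
        x = 20 + 6 * np.sin(2 * np.pi * T / 350.0)
        out = classify_state(traces(T, x, 40 - x))
        assert out.label == "MPDO"

    def test_no_tip_enrichment_is_unpolarized(self):
        flat = np.full_like(T, 5.0)
        out = classify_state(traces(T, flat, flat, mean_ct=np.full_like(T, 4.8)))
        assert out.label == "UNPOLARIZED"

    def test_short_trace_is_explicitly_indeterminate(self):
        tt = np.arange(0.0, 300.0)
        out = classify_state(traces(tt, np.ones(300), np.ones(300)))
        assert out.label == "INDETERMINATE"

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_tip_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        kind = seed % 3
        if kind == 0:
            x1 = np.full_like(T, 120.0) + rng.normal(0, 0.5, len(T))
            x2 = np.full_like(T, 30.0) + rng.normal(0, 0.5, len(T))
        elif kind == 1:
            x1 = 50 + 45 * np.sin(2 * np.pi * T / 280.0)
            x2 = 100 - x1 + rng.normal(0, 0.5, len(T))
        else:
            x1 = np.full_like(T, 90.0) + rng.normal(0, 0.5, len(T))
            x2 = np.full_like(T, 90.0) + rng.normal(0, 0.5, len(T))
        a = classify_state(traces(T, x1, x2))
        b = classify_state(traces(T, x2, x1))
        assert a.label == b.label


class TestOscillationPeriod:
    def test_sinusoid_period_recovered(self):
        x = 10 + 5 * np.sin(2 * np.pi * T / 300.0)
        assert oscillation_period(T, x) == pytest.approx(300.0, abs=2.0)

    def test_constant_trace_has_no_period(self):
        assert oscillation_period(T, np.full_like(T, 3.0)) is None

    def test_transient_cut_applied(self):
        x = np.where(T < 400, 50 + 40 * np.sin(2 * np.pi * T / 50.0), 10.0)
        assert oscillation_period(T, x, transient_cut=450.0) is None


class TestProfiles:
    def test_uniform_field_gives_flat_profile(self, default_mesh):
        snap = snapshot_from(default_mesh, CD=80.0, CT=7.5)
        prof = profile_vs_arclength(snap, default_mesh, species="CT")["CT"]
        assert np.allclose(prof.values, 7.5, rtol=1e-9)
        # bins span at least pole to mid-cell
        assert prof.s_bins[0] <= 0.3
        assert prof.s_bins[-1] >= default_mesh.geom.max_tip_distance

    def test_bin_width_below_mesh_spacing_rejected(self, default_mesh):
        snap = snapshot_from(default_mesh, CT=1.0)
        with pytest.raises(ValueError, match="spacing"):
            profile_vs_arclength(snap, default_mesh, bin_width=0.05)

    def test_profile_aligned_to_dominant_tip(self, default_mesh):
        # put the active zone at tip 2: profile must still decay from s=0
        ct = 100.0 * np.exp(-_dist_from(default_mesh, 2) / 1.0)
        snap = snapshot_from(default_mesh, CT=ct)
        prof = profile_vs_arclength(snap, default_mesh, species="CT")["CT"]
        assert prof.values[0] == max(prof.values)
        assert prof.values[0] > 10 * prof.values[len(prof.values) // 2]


def _dist_from(mesh, tip):
    return analysis._distance_from_tip(mesh, tip)


class TestDecayLength:
    @pytest.mark.parametrize("ell", [0.3, 0.64, 0.72, 1.0, 1.5])
    def test_planted_decay_length_recovered(self, ell):
        s = np.arange(0.125, 5.0, 0.25)
        prof = Profile(s_bins=s, values=120.0 * np.exp(-s / ell), species="CT")
        fit, err = decay_length_fit(prof)
        assert fit == pytest.approx(ell, rel=0.02)
        assert err < 0.05

    def test_noisy_profile_within_tolerance(self, rng):
        s = np.arange(0.125, 3.0, 0.25)
        vals = 100.0 * np.exp(-s / 0.8) * (1 + rng.normal(0, 0.03, len(s)))
        fit, _ = decay_length_fit(Profile(s_bins=s, values=vals, species="CT"))
        assert fit == pytest.approx(0.8, rel=0.1)

    def test_too_few_positive_bins_rejected(self):
        s = np.arange(0.125, 2.0, 0.25)
        vals = -np.ones_like(s)
        vals[:2] = 1.0
        with pytest.raises(ValueError, match="positive bins"):
            decay_length_fit(Profile(s_bins=s, values=vals, species="CT"))


class TestTipToSideRatio:
    def test_uniform_fields_ratio_one(self, default_mesh):
        snap = snapshot_from(default_mesh, CD=80.0, CT=10.0)
        assert tip_to_side_ratio(snap, default_mesh) == pytest.approx(1.0, rel=1e-9)

    def test_tip_enrichment_detected(self, default_mesh):
        ct = 200.0 * np.exp(-default_mesh.s / 0.7)
        snap = snapshot_from(default_mesh, CD=80.0, CT=ct)
        assert tip_to_side_ratio(snap, default_mesh) > 2.0

    def test_overlapping_regions_rejected(self, default_mesh):
        snap = snapshot_from(default_mesh, CD=1.0)
        with pytest.raises(ValueError, match="overlap"):
            tip_to_side_ratio(snap, default_mesh, s_tip=4.5, side_halfwidth=1.0)


class TestTipTraces:
    def test_uniform_ct_equal_traces(self, default_mesh, table1):
        from cdc42polar.integrator import Simulation

        sim = Simulation(table1, mesh=default_mesh)
        sim.state.fields[:, 1] = 12.0
        t1, t2 = sim.tip_values()
        assert t1 == pytest.approx(12.0)
        assert t2 == pytest.approx(12.0)

    def test_oversized_tip_region_rejected(self, default_mesh, table1):
        from cdc42polar.integrator import Simulation, Trajectory

        traj = Simulation(table1, mesh=default_mesh).run(duration=0)
        with pytest.raises(ValueError, match="half-meridian"):
            tip_traces(traj, default_mesh, s_tip=10.0)


class TestPatchTracking:
    def _bump_snaps(self, mesh, centers, width=0.8):
        snaps = []
        for k, c in enumerate(centers):
            d = np.linalg.norm(mesh.nodes - np.asarray(c), axis=1)
            ct = 50.0 * np.exp(-0.5 * (d / width) ** 2) + 1.0
            snaps.append(snapshot_from(mesh, CT=ct, t=25.0 * k))
        return snaps

    def test_stationary_patch(self, default_mesh):
        snaps = self._bump_snaps(default_mesh, [(0, 0, -4.0)] * 8)
        track = patch_tracking(snaps, default_mesh)
        assert track.label == "STATIONARY_PATCH"
        assert track.speeds.max() < 0.01

    def test_travelling_patch_is_wave(self, default_mesh):
        # patch circling the cell circumference at steady speed (net
        # displacement ~ 0, but motion is continuous and uniform)
        ang = np.linspace(0, 2 * np.pi, 14, endpoint=False)
        centers = [(2.0 * np.cos(a), 2.0 * np.sin(a), 0.0) for a in ang]
        track = patch_tracking(self._bump_snaps(default_mesh, centers), default_mesh)
        assert track.label == "WAVE"

    def test_jumping_patches_are_patch_dynamic(self, default_mesh):
        centers = [(2.0, 0, -1.5), (2.0, 0, -1.5), (-2.0, 0, 1.5), (-2.0, 0, 1.5),
                   (0, 2.0, 0.0), (0, 2.0, 0.0), (0, -2.0, -1.0), (0, -2.0, -1.0)]
        track = patch_tracking(self._bump_snaps(default_mesh, centers), default_mesh)
        assert track.label == "PATCH_DYNAMIC"

    def test_no_contrast_no_patch(self, default_mesh):
        snaps = [snapshot_from(default_mesh, CT=5.0, t=25.0 * k) for k in range(6)]
        track = patch_tracking(snaps, default_mesh)
        assert track.label == "NO_PATCH"
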