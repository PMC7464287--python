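"""Reaction kinetics of the Cdc42 GEF/GAP circuit.

Five dynamic surface fields live on the mesh nodes: Cdc42-GDP (``CD``),
Cdc42-GTP (``CT``), the tip GAP (``CGAPI``) and the fast/slow forms of the
side GAP (``CGAPIIfast``/``CGAPIIslow``), all in molecules/μm².  The GEF is
not an independent field: a fixed total pool of ``Ectot`` molecules is
distributed in quasi-static equilibrium between the cytoplasm (``Ec``) and
the membrane, where the local GEF concentration follows Cdc42-GTP through a
linear + quadratic recruitment law.  This conserved pool is the only global
coupling in the reaction terms and is what makes the two tips compete.

GEF-mediated activation is restricted to the tips by the factor
``exp(-s/λ)`` with ``s`` the meridian arc-length distance to the nearest
pole; ``λ = inf`` disables the bias.

Everything here is plain vectorized numpy and serves as the reference
implementation; the integrator's fused kernel (:mod:`._kernels`) is checked
against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SurfaceMesh
from .params import ModelParams

__all__ = [
    "FieldState",
    "FIELD_NAMES",
    "gef_field",
    "refresh_gef",
    "activation_bias",
    "reaction_rates",
    "apply_noise",
    "apply_langevin_noise",
    "initial_state",
]

FIELD_NAMES = ("CD", "CT", "CGAPI", "CGAPIIfast", "CGAPIIslow")
_CD, _CT, _GI, _GF, _GS = range(5)

#: concentrations this far below zero are roundoff, anything lower is an error
NEGATIVE_TOL = -1e-9


@dataclass
class FieldState:
    """Per-node concentrations of the five dynamic species at time ``t``.

    ``fields`` is an (N, 5) array in the order of :data:`FIELD_NAMES`.  The
    GEF pool is carried as the cytoplasmic count ``Ec`` plus the recruitment
    integrand ``gef_w = (k1p CT + k2p CT²)/V``; the membrane GEF surface
    density is the product ``CGEF = gef_w · Ec`` and satisfies
    ``Ec + ∫ CGEF da = Ectot`` identically.
    """

    fields: np.ndarray
    gef_w: np.ndarray
    Ec: float
    t: float = 0.0

    @property
    def CD(self) -> np.ndarray:
        return self.fields[:, _CD]

    @property
    def CT(self) -> np.ndarray:
        return self.fields[:, _CT]

    @property
    def CGAPI(self) -> np.ndarray:
        return self.fields[:, _GI]

    @property
    def CGAPIIfast(self) -> np.ndarray:
        return self.fields[:, _GF]

    @property
    def CGAPIIslow(self) -> np.ndarray:
        return self.fields[:, _GS]

    @property
    def CGEF(self) -> np.ndarray:
        """Membrane GEF surface concentration (molecules/μm²)."""
        return self.gef_w * self.Ec

    def copy(self) -> "FieldState":
        return FieldState(self.fields.copy(), self.gef_w.copy(), self.Ec, self.t)


def gef_field(
    CT: np.ndarray, p: ModelParams, mesh: SurfaceMesh
) -> tuple[np.ndarray, float]:
    """Quasi-static membrane GEF field and cytoplasmic GEF count.

    The membrane density is ``CGEF = (k1p CT + k2p CT²) Ec / V`` with the
    cytoplasmic count ``Ec = Ectot / (1 + ∫ (k1p CT + k2p CT²)/V da)``, so
    that membrane plus cytoplasm always sum to the fixed total pool.
    """
    w = (p.k1p * CT + p.k2p * CT * CT) / p.volume
    Ec = p.Ectot / (1.0 + float(np.dot(mesh.areas, w)))
    return w * Ec, Ec


def refresh_gef(state: FieldState, p: ModelParams, mesh: SurfaceMesh) -> None:
    """Re-equilibrate the GEF pool to the current Cdc42-GTP field."""
    w = (p.k1p * state.CT + p.k2p * state.CT**2) / p.volume
    state.gef_w = w
    state.Ec = p.Ectot / (1.0 + float(np.dot(mesh.areas, w)))


def activation_bias(p: ModelParams, mesh: SurfaceMesh) -> np.ndarray:
    """Tip-bias factor exp(-s/λ) per node (all ones when λ is infinite)."""
    if np.isinf(p.lam):
        return np.ones(mesh.n_nodes)
    return np.exp(-mesh.s / p.lam)


def _check_nonnegative(fields: np.ndarray) -> None:
    mins = fields.min(axis=0)
    if mins.min() < NEGATIVE_TOL:
        k = int(np.argmin(mins))
        raise ValueError(
            f"{FIELD_NAMES[k]} is negative beyond tolerance "
            f"(min {mins[k]:.3e}): numerical instability?"
        )


def reaction_rates(
    state: FieldState,
    p: ModelParams,
    mesh: SurfaceMesh,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Local reaction terms (no diffusion) for all five fields, (N, 5).

    ``state`` must carry a GEF pool equilibrated to its current Cdc42-GTP
    field (the quasi-static assumption).  The deterministic ±rnoise·CD
    exchange is included only in ``noise_mode='deterministic'``; the
    stochastic variant is applied separately (:func:`apply_noise`).
    """
    F = state.fields
    _check_nonnegative(F)
    if bias is None:
        bias = activation_bias(p, mesh)
    CD, CT = F[:, _CD], F[:, _CT]
    GI, GF, GS = F[:, _GI], F[:, _GF], F[:, _GS]
    out = np.empty_like(F)
    hydrolysis = (p.k1n + p.k2n * GI + p.k3n * GF + p.k8n * GS) * CT
    activation = p.k0p * bias * state.CGEF * CD
    out[:, _CD] = p.jDp + hydrolysis - activation - p.rD * CD
    out[:, _CT] = activation - hydrolysis - p.rT * CT
    if p.noise_mode in ("deterministic", "langevin"):
        out[:, _CD] -= p.rnoise * CD
        out[:, _CT] += p.rnoise * CD
    cth = CT**p.h
    out[:, _GI] = p.k4n * cth / (p.ksat**p.h + cth) - p.rGAPI * GI
    fast_to_slow = p.k6n * GF
    slow_to_fast = p.k7n * GS * CT
    out[:, _GF] = p.k5n * CT - fast_to_slow + slow_to_fast - p.rGAPIIfast * GF
    out[:, _GS] = fast_to_slow - slow_to_fast - p.rGAPIIslow * GS
    return out


def apply_noise(
    state: FieldState,
    p: ModelParams,
    mesh: SurfaceMesh,
    dt: float,
    rng: np.random.Generator,
) -> int:
    """Random activation: convert whole Cdc42-GDP molecules to Cdc42-GTP.

    Per node the number of converted molecules is Poisson with mean
    ``rnoise · CD_i · a_i · dt``; this is realised equivalently by drawing
    the cell-wide event count once and placing events with probability
    proportional to the per-node rates.  Conversion is capped by the GDP
    molecules actually present, total Cdc42 mass is unchanged exactly, and
    the number of events applied is returned.  The caller is responsible for
    re-equilibrating the GEF pool afterwards.
    """
    if p.rnoise == 0.0 or p.noise_mode != "stochastic":
        return 0
    F = state.fields
    rates = p.rnoise * dt * F[:, _CD] * mesh.areas  # expected events per node
    total = float(rates.sum())
    if total <= 0.0:
        return 0
    n_events = int(rng.poisson(total))
    if n_events == 0:
        return 0
    nodes = rng.choice(mesh.n_nodes, size=n_events, p=rates / total)
    nodes, counts = np.unique(nodes, return_counts=True)
    moles = np.minimum(counts.astype(float), F[nodes, _CD] * mesh.areas[nodes])
    dc = moles / mesh.areas[nodes]
    F[nodes, _CD] = np.maximum(F[nodes, _CD] - dc, 0.0)  # guard cap roundoff
    F[nodes, _CT] += dc
    return n_events


def apply_langevin_noise(
    state: FieldState,
    p: ModelParams,
    mesh: SurfaceMesh,
    dt: float,
    rng: np.random.Generator,
) -> None:
    """Fluctuating part of random activation in the chemical-Langevin sense.

    The mean conversion ``rnoise·CD`` is integrated with the reaction terms
    (see :func:`reaction_rates`); this adds the zero-mean Gaussian exchange
    whose per-node variance matches the Poisson molecule-count statistics,
    ``σ_i = sqrt(rnoise · CD_i · dt / a_i)``.  The exchange is clipped to the
    physically available molecules, conserving total Cdc42 exactly and
    keeping both fields non-negative.
    """
    if p.rnoise == 0.0 or p.noise_mode != "langevin":
        return
    F = state.fields
    sig = np.sqrt(p.rnoise * dt * F[:, _CD] / mesh.areas)
    q = sig * rng.standard_normal(mesh.n_nodes)
    np.clip(q, -F[:, _CT], F[:, _CD], out=q)
    F[:, _CD] -= q
    F[:, _CT] += q


def initial_state(
    p: ModelParams,
    mesh: SurfaceMesh,
    rng: np.random.Generator,
    fluctuation: float = 0.01,
) -> FieldState:
    """Unpolarized start: CD at its activation-free steady state jDp/rD.

    Each node gets a relative fluctuation uniform in ±``fluctuation``, plus a
    small random Cdc42-GTP seed field uniform in [0, fluctuation·jDp/rD].
    GAP fields start at zero; the GEF pool is equilibrated to the initial
    Cdc42-GTP.
    """
    n = mesh.n_nodes
    cd0 = p.jDp / p.rD
    F = np.zeros((n, 5))
    F[:, _CD] = cd0 * (1.0 + rng.uniform(-fluctuation, fluctuation, size=n))
    F[:, _CT] = rng.uniform(0.0, fluctuation * cd0, size=n)
    state = FieldState(fields=F, gef_w=np.zeros(n), Ec=p.Ectot, t=0.0)
    refresh_gef(state, p, mesh)
    return state
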