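"""Model parameters: rate constants, geometry, and run settings.

Attribute names follow the conventional symbols of the reaction-diffusion
model: ``D*`` are membrane diffusion coefficients, ``k*p``/``k*n`` are
positive/negative-feedback rate constants, ``r*`` are membrane dissociation
rates, and ``lam`` is the tip-bias length scale (``lambda`` in config files;
``inf`` turns the bias off).  Defaults are the reference parameter set of the
fission-yeast Cdc42 model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass

from .geometry import CellGeometry

__all__ = ["ModelParams", "load_config", "params_from_config"]

NOISE_MODES = ("langevin", "stochastic", "deterministic", "off")

#: config-file key -> attribute name (only where they differ)
_CONFIG_ALIASES = {"lambda": "lam"}


@dataclass(frozen=True)
class ModelParams:
    # diffusion coefficients (μm²/s)
    DT: float = 0.02          # Cdc42-GTP
    DD: float = 0.2           # Cdc42-GDP
    DGAPI: float = 0.03       # GAP_I
    DGAPIIfast: float = 0.0625  # fast-diffusing GAP_II
    DGAPIIslow: float = 0.005   # slow-diffusing GAP_II

    # negative feedback / hydrolysis
    k1n: float = 0.000625     # 1/s, spontaneous Cdc42-GTP hydrolysis
    k2n: float = 0.00325      # μm²/s, GAP_I-mediated hydrolysis
    k3n: float = 0.00125      # μm²/s, fast-GAP_II-mediated hydrolysis
    k8n: float = 0.0005       # μm²/s, slow-GAP_II-mediated hydrolysis
    k4n: float = 250.0        # 1/μm²/s, Cdc42-GTP-mediated GAP_I recruitment
    k5n: float = 0.03         # 1/s, Cdc42-GTP-mediated GAP_II recruitment
    k6n: float = 2.0          # 1/s, fast -> slow GAP_II conversion
    k7n: float = 0.025        # μm²/s, Cdc42-GTP-mediated slow -> fast conversion
    ksat: float = 600.0       # 1/μm², GAP_I recruitment saturation
    h: float = 2.0            # Hill exponent of GAP_I recruitment

    # positive feedback / activation
    k0p: float = 0.0025       # μm²/s, GEF-mediated Cdc42-GDP activation
    k1p: float = 0.5          # μm³, linear GEF recruitment coefficient
    k2p: float = 0.1          # μm⁵, quadratic GEF recruitment coefficient
    Ectot: float = 250.0      # molecules, total GEF pool

    # membrane association / dissociation
    jDp: float = 2.4          # 1/s/μm², Cdc42-GDP association flux
    rT: float = 0.005         # 1/s, Cdc42-GTP dissociation
    rD: float = 0.03          # 1/s, Cdc42-GDP dissociation
    rGAPI: float = 0.01       # 1/s
    rGAPIIfast: float = 0.0125  # 1/s
    rGAPIIslow: float = 0.0025  # 1/s

    rnoise: float = 0.0021    # 1/s, random Cdc42-GDP activation
    lam: float = 2.5          # μm, tip-bias length scale (inf = unbiased)

    # geometry and run settings
    L: float = 8.0            # μm, tip-to-tip cell length
    R: float = 2.0            # μm, radius
    target_cell_area: float = 0.03  # μm², mesh resolution
    dt: float = 0.01          # s, explicit time step
    duration: float = 1200.0  # s, simulated time
    seed: int = 0
    #: how the random-activation rate rnoise is realised:
    #: "langevin"      - deterministic mean conversion plus a zero-mean
    #:                   Gaussian exchange with Poisson-matched variance
    #:                   (chemical Langevin; the default)
    #: "stochastic"    - whole-molecule Poisson conversion events
    #: "deterministic" - the mean conversion term only
    #: "off"           - no random activation at all
    noise_mode: str = "langevin"

    def __post_init__(self) -> None:
        for name in (
            "DT", "DD", "DGAPI", "DGAPIIfast", "DGAPIIslow",
            "k1n", "k2n", "k3n", "k4n", "k5n", "k6n", "k7n", "k8n",
            "ksat", "k0p", "k1p", "k2p", "Ectot", "jDp",
            "rT", "rD", "rGAPI", "rGAPIIfast", "rGAPIIslow", "rnoise",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.h < 1:
            raise ValueError("Hill exponent h must be >= 1")
        if self.lam <= 0:
            raise ValueError("lam must be positive (use inf for no tip bias)")
        if self.dt <= 0 or self.duration < 0:
            raise ValueError("dt must be positive and duration non-negative")
        if self.noise_mode not in NOISE_MODES:
            raise ValueError(f"noise_mode must be one of {NOISE_MODES}")
        # geometry invariants checked by CellGeometry
        _ = self.geometry

    @property
    def geometry(self) -> CellGeometry:
        return CellGeometry(L=self.L, R=self.R, target_cell_area=self.target_cell_area)

    @property
    def volume(self) -> float:
        """Cell volume πR²(L-2R) + (4/3)πR³ (μm³); derived, never stored."""
        return self.geometry.volume

    @property
    def max_diffusivity(self) -> float:
        return max(self.DT, self.DD, self.DGAPI, self.DGAPIIfast, self.DGAPIIslow)

    def replace(self, **overrides) -> "ModelParams":
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lambda"] = d.pop("lam")
        if math.isinf(d["lambda"]):
            d["lambda"] = "inf"
        return d

    def digest(self) -> str:
        """Short stable hash of the full parameter set, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def params_from_config(cfg: dict) -> ModelParams:
    """Build parameters from a flat config mapping.

    Keys use the conventional symbol names (``lambda`` for the tip-bias
    scale).  Unknown keys raise ``ValueError``.
    """
    valid = {f.name for f in dataclasses.fields(ModelParams)}
    kwargs = {}
    for key, value in cfg.items():
        attr = _CONFIG_ALIASES.get(key, key)
        if attr not in valid:
            raise ValueError(f"unknown config key: {key!r}")
        if attr == "lam" and isinstance(value, str):
            value = float(value)
        kwargs[attr] = value
    return ModelParams(**kwargs)


def load_config(path) -> ModelParams:
    """Read a flat YAML (or JSON) parameter file."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    return params_from_config(cfg)
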