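"""Site configurations, noise specifications and stage thresholds.

Defaults for the two study springs (OSP = One Hundred Spring Plain,
Beowulf) live in a packaged YAML file; :func:`site_config` materialises
them into a :class:`SiteConfig`, solving the O2 slab parameters
``(k1, L_f)`` from each site's surface-flux and Thiele-modulus
constraints at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .oxygen import ReactionDiffusionModel, solve_slab_parameters

__all__ = [
    "CommunityTrajectory",
    "SiteConfig",
    "NoiseSpec",
    "StageThresholds",
    "site_config",
    "load_site_defaults",
    "SITES",
]


@dataclass
class CommunityTrajectory:
    """Parametric mean community composition over mat development.

    The early-colonising rod lithoautotroph starts dominant and declines
    linearly (fraction/day, floored); the Fe(II)-oxidizer holds a
    constant fraction; heterotrophic archaea share the remaining mass
    with relative weights that rise logistically around a midpoint day.
    """

    rod_taxon: str = "Hydrogenobaculum"
    rod_start: float = 0.85
    rod_start_day: float = 4.0
    rod_decline_per_day: float = 0.01
    rod_floor: float = 0.01
    feox_taxon: str = "Metallosphaera yellowstonensis"
    feox_fraction: float = 0.15
    het_midpoint_day: float = 45.0
    het_steepness: float = 0.15
    heterotrophs: dict[str, float] = field(
        default_factory=lambda: {
            "Geoarchaeota": 0.55,
            "Novel archaeal group 2": 0.30,
            "Other Sulfolobales": 0.07,
            "Thaumarchaeota": 0.05,
            "Novel archaeal group 3": 0.03,
        }
    )

    @property
    def taxa(self) -> list[str]:
        return [self.rod_taxon, self.feox_taxon, *self.heterotrophs]

    def mean_proportions(self, t: float) -> dict[str, float]:
        """Deterministic composition at day ``t``; sums to 1 exactly."""
        rod = self.rod_start - self.rod_decline_per_day * max(t - self.rod_start_day, 0.0)
        rod = min(max(rod, self.rod_floor), 1.0 - self.feox_fraction)
        remainder = 1.0 - rod - self.feox_fraction
        if remainder < -1e-12:
            raise ValueError("trajectory produced negative proportions")
        remainder = max(remainder, 0.0)
        weights = {
            name: w / (1.0 + np.exp(-self.het_steepness * (t - self.het_midpoint_day)))
            for name, w in self.heterotrophs.items()
        }
        total_w = sum(weights.values())
        props = {self.rod_taxon: rod, self.feox_taxon: self.feox_fraction}
        for name, w in weights.items():
            props[name] = remainder * w / total_w if total_w > 0 else 0.0
        norm = sum(props.values())
        return {name: p / norm for name, p in props.items()}


@dataclass
class SiteConfig:
    """Generating parameters for one spring."""

    site_name: str
    fe_k: float                 # day^-1
    fe_x0: float                # umol cm^-2
    dna_r: float                # day^-1
    dna_x0: float               # ng cm^-2
    coloniz_rate_rod: float     # cells cm^-2 day^-1
    coloniz_rate_coccus: float  # cells cm^-2 day^-1
    o2_bulk: float              # uM
    profile_params: tuple[float, float, float]  # (k1 s^-1, D_e cm^2/s, L_f cm)
    as_fe_ratio: float
    p_fe_ratio: float
    w_fe_ratio: float
    community_trajectory: CommunityTrajectory = field(default_factory=CommunityTrajectory)
    fe_detection_limit: float = 0.05    # umol cm^-2
    extraction_volume_l: float = 0.05
    slide_area_cm2: float = 18.75
    channel_velocity_cm_s: float | None = None
    reynolds: float | None = None

    def __post_init__(self) -> None:
        for name in ("fe_k", "fe_x0", "dna_r", "dna_x0", "coloniz_rate_rod",
                     "coloniz_rate_coccus", "o2_bulk"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("as_fe_ratio", "p_fe_ratio", "w_fe_ratio"):
            r = getattr(self, name)
            if not (0 < r <= 2):
                raise ValueError(f"{name} must lie in (0, 2]")

    def reaction_diffusion_model(self, order: str = "first") -> ReactionDiffusionModel:
        k1, d_e, l_f = self.profile_params
        return ReactionDiffusionModel(
            kinetic_order=order, k1=k1, D_e=d_e, L_f=l_f, C0=self.o2_bulk
        )


@dataclass
class NoiseSpec:
    """Noise model for the synthetic generators.

    ``scale`` is a coefficient of variation for lognormal/gaussian noise
    and the total concentration for dirichlet draws; Poisson noise has
    no free scale.  ``kind='none'`` returns deterministic means.
    """

    kind: str = "none"  # none | lognormal | gaussian | poisson | dirichlet
    scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "lognormal", "gaussian", "poisson", "dirichlet"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("scale must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class StageThresholds:
    """Rule thresholds for the four-stage mat development classifier."""

    mature_depth_mm: float = 5.0       # stage IV
    gradient_depth_mm: float = 2.0     # stage III
    heterotroph_fraction: float = 0.25 # stage III


def load_site_defaults() -> dict:
    """Raw per-site defaults from the packaged YAML."""
    text = resources.files("ferromat").joinpath("data/sites.yaml").read_text()
    return yaml.safe_load(text)


def site_config(site: str, defaults: dict | None = None) -> SiteConfig:
    """Build a :class:`SiteConfig` for ``site`` ('osp' or 'beowulf').

    The slab parameters are solved so that the closed-form first-order
    surface flux and Thiele modulus match the site's configured values
    at the configured diffusivity and bulk O2.
    """
    raw = (defaults or load_site_defaults())
    if site not in raw:
        raise KeyError(f"unknown site {site!r}; available: {sorted(raw)}")
    # YAML 1.1 reads exponent literals without a sign ("3.7e6") as strings
    d = {k: (float(v) if isinstance(v, str) and k != "site_name" else v)
         for k, v in raw[site].items()}
    k1, l_f = solve_slab_parameters(
        flux=float(d.pop("o2_flux")),
        phi=float(d.pop("thiele_modulus")),
        D_e=float(d["d_e"]),
        C0=float(d["o2_bulk"]),
    )
    d_e = float(d.pop("d_e"))
    comm = d.pop("community", {})
    traj = CommunityTrajectory(**comm) if comm else CommunityTrajectory()
    return SiteConfig(profile_params=(k1, d_e, l_f), community_trajectory=traj, **d)


class _SiteRegistry:
    """Lazy mapping of site name -> default SiteConfig."""

    def __init__(self) -> None:
        self._cache: dict[str, SiteConfig] = {}

    def __getitem__(self, site: str) -> SiteConfig:
        if site not in self._cache:
            self._cache[site] = site_config(site)
        return self._cache[site]

    def __iter__(self):
        return iter(load_site_defaults())


SITES = _SiteRegistry()
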