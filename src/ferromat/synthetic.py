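"""Synthetic field data with the statistical structure the pipeline assumes.

The study's raw slide data are not deposited, so every input type the
analysis consumes — Fe and DNA accretion series, O2 microprofiles, SEM
cell-count fields, taxon x sample community tables, and oxalate/ICP
extraction tables — is generated here from per-site configurations
whose defaults are the study's fitted values.  Noiseless output lies
exactly on the generating model (so fits round-trip to machine
precision); noisy output uses a noise family matched to each
variable's support: multiplicative lognormal for positive accretion
and DNA values, additive gaussian clipped at zero for microprofiles,
Poisson for cell counts, Dirichlet for compositions.  All randomness
flows through an explicit integer seed on :class:`NoiseSpec`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .colonization import CellCountObservation
from .community import AbundanceTable
from .config import NoiseSpec, SiteConfig
from .constants import UM_PER_CM, molar_mass
from .geochem import ExtractionRecord
from .kinetics import TimeSeries
from .oxygen import Microprofile, ReactionDiffusionModel, dimensionless_profile

__all__ = [
    "gen_accretion_series",
    "gen_dna_series",
    "gen_microprofile",
    "gen_count_fields",
    "gen_community_table",
    "gen_extraction_table",
    "DEFAULT_COPY_NUMBERS",
]

#: 16S rRNA gene copies per taxon; Hydrogenobaculum carries two operons.
DEFAULT_COPY_NUMBERS = {"Hydrogenobaculum": 2.0}

_NONE = NoiseSpec()


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


def _exponential_series(
    x0: float, k: float, times: np.ndarray, noise: NoiseSpec,
    detection_limit: float, units: str,
) -> TimeSeries:
    mean = x0 * np.exp(k * times)
    if noise.kind == "none":
        x = mean
    elif noise.kind == "lognormal":
        # multiplicative factor with unit mean and CV = scale
        sigma2 = np.log1p(noise.scale**2)
        factors = noise.rng().lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=mean.shape)
        x = mean * factors
    else:
        raise ValueError(f"noise kind {noise.kind!r} not supported for accretion series")
    censored = x < detection_limit
    x = np.where(censored, detection_limit, x)
    return TimeSeries(t=times, x=x, censored=censored, units=units)


def gen_accretion_series(
    config: SiteConfig, times, noise: NoiseSpec = _NONE,
    detection_limit: float | None = None,
) -> TimeSeries:
    """Fe(III)-oxide accretion series x(t) = fe_x0 * exp(fe_k * t).

    Values below the detection limit are reported at the limit and
    flagged censored, mimicking slides with no visible Fe(III)-oxide.
    """
    times = _check_times(times)
    limit = detection_limit if detection_limit is not None else config.fe_detection_limit
    return _exponential_series(
        config.fe_x0, config.fe_k, times, noise, limit, units="umol Fe cm^-2"
    )


def gen_dna_series(config: SiteConfig, times, noise: NoiseSpec = _NONE) -> TimeSeries:
    """Total community DNA series x(t) = dna_x0 * exp(dna_r * t), ng/cm^2."""
    times = _check_times(times)
    return _exponential_series(
        config.dna_x0, config.dna_r, times, noise, detection_limit=0.0,
        units="ng DNA cm^-2",
    )


def gen_microprofile(
    model: ReactionDiffusionModel, z_grid, noise: NoiseSpec = _NONE,
) -> Microprofile:
    """O2 depth profile C(z) = C0 * u(z / L_f) on a micrometre grid.

    Gaussian electrode noise (sd = scale * C0) is added then clipped at
    zero; the grid must stay inside the slab (z_max <= L_f).
    """
    z = np.asarray(z_grid, dtype=float)
    if z.size == 0 or z[0] < 0:
        raise ValueError("z_grid must start at or below the interface (z >= 0)")
    lf_um = model.L_f * UM_PER_CM
    if z[-1] > lf_um * (1 + 1e-12):
        raise ValueError("z_grid extends beyond the mat thickness L_f")
    zeta = np.clip(z / lf_um, 0.0, 1.0)
    C = model.C0 * dimensionless_profile(model.kinetic_order, model.phi, zeta)
    if noise.kind == "gaussian":
        C = C + noise.rng().normal(0.0, noise.scale * model.C0, size=C.shape)
    elif noise.kind != "none":
        raise ValueError(f"noise kind {noise.kind!r} not supported for microprofiles")
    C = np.clip(C, 0.0, None)
    return Microprofile(z=z, C=C, C_bulk=model.C0)


def gen_count_fields(
    rate: float, times, field_area: float = 1e-4, n_fields: int = 4,
    noise: NoiseSpec = _NONE, morphotype: str = "rod",
) -> list[CellCountObservation]:
    """SEM field-of-view counts for one morphotype.

    Expected count per field is rate * t * field_area; Poisson noise
    when requested, otherwise rounded deterministic means.
    """
    if rate < 0:
        raise ValueError("colonization rate must be nonnegative")
    if field_area <= 0:
        raise ValueError("field_area must be positive")
    if n_fields < 1:
        raise ValueError("need at least one field per time point")
    times = _check_times(times)
    rng = noise.rng()
    out: list[CellCountObservation] = []
    for t in times:
        expected = rate * t * field_area
        for i in range(n_fields):
            if noise.kind == "poisson":
                n = int(rng.poisson(expected))
            elif noise.kind == "none":
                n = int(round(expected))
            else:
                raise ValueError(f"noise kind {noise.kind!r} not supported for counts")
            out.append(CellCountObservation(
                t=float(t), field_area=field_area,
                counts={morphotype: n}, field_id=f"d{t:g}_f{i + 1}",
            ))
    return out


def _sample_id(site: str, day: float) -> str:
    return f"{site}_day{int(round(day)):02d}"


def gen_community_table(
    config: SiteConfig, times, noise: NoiseSpec = _NONE,
    copy_numbers: dict[str, float] | None = None,
) -> AbundanceTable:
    """Taxon x sample table of relative abundances over mat development.

    The mean trajectory comes from the site's parametric community
    model (declining rod lithoautotroph, constant Fe(II)-oxidizer,
    logistically rising heterotrophs); Dirichlet noise draws
    compositions around the mean with concentration = scale.  Columns
    are labelled ``site_dayNN`` and always sum to 1.
    """
    times = _check_times(times)
    if np.any(times > 100):
        raise ValueError("community trajectory is defined for days 0-100")
    traj = config.community_trajectory
    taxa = traj.taxa
    rng = noise.rng()
    cols = {}
    for t in times:
        mean = np.array([traj.mean_proportions(float(t))[tx] for tx in taxa])
        if noise.kind == "dirichlet":
            pos = mean > 0
            draw = np.zeros_like(mean)
            draw[pos] = rng.dirichlet(noise.scale * mean[pos])
            draw[pos] *= mean[pos].sum()  # preserve mass of structurally-zero taxa
            props = draw
        elif noise.kind == "none":
            props = mean
        else:
            raise ValueError(f"noise kind {noise.kind!r} not supported for communities")
        props = props / props.sum()
        cols[_sample_id(config.site_name, t)] = props
    values = pd.DataFrame(cols, index=pd.Index(taxa, name="taxon"))
    meta = pd.DataFrame(
        {"site": config.site_name, "day": [float(t) for t in times], "depth_zone": "none"},
        index=list(values.columns),
    )
    copies = dict(DEFAULT_COPY_NUMBERS if copy_numbers is None else copy_numbers)
    cn = pd.Series({tx: copies.get(tx, 1.0) for tx in taxa})
    return AbundanceTable(values=values, mode="proportions",
                          copy_numbers=cn, sample_meta=meta)


def gen_extraction_table(
    config: SiteConfig, times, noise: NoiseSpec = _NONE,
) -> list[ExtractionRecord]:
    """Oxalate-extraction ICP tables tracking the Fe accretion series.

    Fe concentrations (mg/L) follow the accretion curve through the
    extraction volume and slide area (lognormal noise multiplies the
    Fe loading); As, P and W concentrations are set so the molar
    ratios equal the site's configured oxyanion:Fe ratios.
    """
    if config.extraction_volume_l <= 0 or config.slide_area_cm2 <= 0:
        raise ValueError("extraction volume and slide area must be positive")
    fe = gen_accretion_series(config, times, noise, detection_limit=0.0)
    ratios = {"As": config.as_fe_ratio, "P": config.p_fe_ratio, "W": config.w_fe_ratio}
    records = []
    for t, loading in zip(fe.t, fe.x):
        fe_umol = loading * config.slide_area_cm2
        conc = {"Fe": fe_umol * molar_mass("Fe") / 1000.0 / config.extraction_volume_l}
        for el, r in ratios.items():
            conc[el] = r * fe_umol * molar_mass(el) / 1000.0 / config.extraction_volume_l
        records.append(ExtractionRecord(
            t=float(t), concentrations=conc,
            extraction_volume=config.extraction_volume_l,
            slide_area=config.slide_area_cm2, site=config.site_name,
        ))
    return records
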