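"""Colonization-rate estimation from SEM field-of-view cell counts.

Early mat assembly is quantified by counting cells of each morphotype
(rod-shaped bacteria, coccus-shaped archaea) in a handful of random
microscope fields per slide.  Counts become areal densities
(cells/cm^2) and densities become colonization rates (cells/cm^2/day)
via a through-origin regression — a sterile slide carries no cells at
deployment, so the density-vs-time line is forced through zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellCountObservation",
    "areal_density",
    "colonization_rate",
    "rate_ratio",
]


@dataclass
class CellCountObservation:
    """Cell counts per morphotype in one microscope field."""

    t: float                     # days since deployment
    field_area: float            # cm^2
    counts: dict[str, int] = field(default_factory=dict)
    field_id: str = ""

    def __post_init__(self) -> None:
        if self.field_area <= 0:
            raise ValueError("field_area must be positive")
        if self.t < 0:
            raise ValueError("time must be nonnegative")
        for morph, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for morphotype {morph!r}")


def areal_density(obs: CellCountObservation) -> dict[str, float]:
    """Cells per cm^2 for each morphotype in one field."""
    return {morph: n / obs.field_area for morph, n in obs.counts.items()}


def colonization_rate(
    observations: list[CellCountObservation], morphotype: str
) -> tuple[float, float]:
    """Colonization rate (cells/cm^2/day) and spread for one morphotype.

    The rate is the through-origin least-squares slope of mean areal
    density against time; the spread is the sample SD of per-field
    slopes (density_i / t_i), reflecting between-field variability.
    For a single time point the estimate reduces to density / t.
    """
    pts = [(o.t, areal_density(o).get(morphotype))
           for o in observations if morphotype in o.counts]
    if not pts:
        raise ValueError(f"no observations for morphotype {morphotype!r}")
    pts = [(t, d) for t, d in pts if d is not None]
    if all(t == 0 for t, _ in pts):
        raise ValueError("all observations at t = 0; rate undefined")

    # mean density per time point, then through-origin slope
    by_time: dict[float, list[float]] = {}
    for t, d in pts:
        by_time.setdefault(t, []).append(d)
    times = np.array(sorted(by_time))
    means = np.array([np.mean(by_time[t]) for t in times])
    rate = float(np.sum(times * means) / np.sum(times**2))

    per_field = np.array([d / t for t, d in pts if t > 0])
    sd = float(np.std(per_field, ddof=1)) if per_field.size > 1 else 0.0
    return rate, sd


def rate_ratio(rate_a: float, rate_b: float) -> float:
    """Ratio of two colonization rates (dimensionless)."""
    if rate_b == 0:
        raise ZeroDivisionError("denominator rate is zero; ratio undefined")
    return rate_a / rate_b
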