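"""Steady-state O2 reaction-diffusion modelling of Fe(III)-oxide mats.

An accreting mat is treated as a homogeneous slab of thickness ``L_f``
(cm) with effective O2 diffusivity ``D_e`` (cm^2/s) and bulk interface
concentration ``C0`` (uM).  At steady state the dimensionless profile
``u(zeta) = C/C0`` over ``zeta = z/L_f`` depends on a single group, the
Thiele modulus::

    phi^2 = k1 * L_f^2 / D_e

For first-order consumption (rate constant ``k1``, 1/s) the slab
solution with a no-flux bottom boundary is

    u = cosh(phi * (1 - zeta)) / cosh(phi)

while the zero-order analogue is the quadratic

    u = (phi^2 * zeta^2) / 2 - phi^2 * zeta + 1

clipped at zero below the depth where all O2 is consumed.  phi >> 1
means consumption outruns diffusive supply: the mat is diffusion
limited and O2 penetrates only a thin surface layer.

Surface flux follows Fick's first law, J = -D_e dC/dz at z = 0; the
closed form for the first-order slab is ``C0 * sqrt(D_e*k1) * tanh(phi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import UM_PER_CM, UM_TO_UMOL_PER_CM3

__all__ = [
    "Microprofile",
    "ReactionDiffusionModel",
    "FluxEstimate",
    "dimensionless_profile",
    "estimate_flux",
    "thiele_modulus",
    "classify_limitation",
    "fit_profile",
    "penetration_depth",
    "surface_flux_closed_form",
    "solve_slab_parameters",
]

#: uM/um -> (umol/cm3)/cm
_GRADIENT_TO_CGS = UM_TO_UMOL_PER_CM3 * UM_PER_CM


@dataclass
class Microprofile:
    """Measured or simulated O2 depth profile.

    ``z`` is depth in micrometres, zero at the mat-water interface and
    increasing into the mat; ``C`` is O2 in uM.
    """

    z: np.ndarray
    C: np.ndarray
    C_bulk: float
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.z.shape != self.C.shape:
            raise ValueError("z and C must have the same length")
        if self.z.size and np.any(np.diff(self.z) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.C < 0):
            raise ValueError("concentrations must be nonnegative")
        if self.C_bulk <= 0:
            raise ValueError("C_bulk must be positive")


@dataclass
class ReactionDiffusionModel:
    """Slab parameters: kinetics, diffusivity, thickness, bulk O2."""

    kinetic_order: str = "first"  # "first" (k1, 1/s) or "zero" (k0, uM/s)
    k1: float = 0.0
    D_e: float = 4.5e-5
    L_f: float = 0.1
    C0: float = 55.0

    def __post_init__(self) -> None:
        if self.kinetic_order not in ("first", "zero"):
            raise ValueError("kinetic_order must be 'first' or 'zero'")
        if self.D_e <= 0 or self.L_f <= 0:
            raise ValueError("D_e and L_f must be positive")
        if self.k1 < 0:
            raise ValueError("rate constant must be nonnegative")
        if self.C0 < 0:
            raise ValueError("C0 must be nonnegative")

    @property
    def phi(self) -> float:
        return thiele_modulus(self.k1, self.L_f, self.D_e)


@dataclass
class FluxEstimate:
    """Diffusive O2 flux into the mat (positive for consumption)."""

    J: float                     # umol cm^-2 s^-1
    gradient: float              # uM/um (signed OLS slope)
    window: tuple[int, ...] = field(default_factory=tuple)
    D_e: float = 4.5e-5


def dimensionless_profile(order: str, phi: float, zeta) -> np.ndarray | float:
    """Evaluate u(zeta) = C/C0 for the chosen kinetic order.

    The first-order cosh form is computed in log space so large phi
    (steep, strongly diffusion-limited profiles) does not overflow.
    The zero-order quadratic is clipped at zero where it goes anoxic.
    """
    zeta_arr = np.asarray(zeta, dtype=float)
    if phi < 0:
        raise ValueError("phi must be nonnegative")
    if np.any(zeta_arr < 0) or np.any(zeta_arr > 1):
        raise ValueError("zeta must lie in [0, 1]")
    if order == "first":
        # cosh(phi*(1-zeta))/cosh(phi) = exp(-phi*zeta)*(1+exp(-2phi(1-zeta)))/(1+exp(-2phi))
        a = phi * (1.0 - zeta_arr)
        u = np.exp(a - phi) * (1.0 + np.exp(-2.0 * a)) / (1.0 + np.exp(-2.0 * phi))
    elif order == "zero":
        u = (phi**2 * zeta_arr**2) / 2.0 - phi**2 * zeta_arr + 1.0
        u = np.clip(u, 0.0, None)
    else:
        raise ValueError("order must be 'first' or 'zero'")
    return u if np.ndim(zeta) else float(u)


def thiele_modulus(k1: float, L_f: float, D_e: float) -> float:
    """phi = sqrt(k1 * L_f^2 / D_e)."""
    if k1 < 0 or L_f <= 0 or D_e <= 0:
        raise ValueError("k1 must be >= 0 and L_f, D_e positive")
    return float(np.sqrt(k1 * L_f**2 / D_e))


def classify_limitation(phi: float, threshold: float = 1.0) -> str:
    """Diffusion limited (phi > threshold), reaction limited, or balanced."""
    if phi > threshold:
        return "diffusion_limited"
    if phi < threshold:
        return "reaction_limited"
    return "balanced"


def estimate_flux(profile: Microprofile, D_e: float, window: int = 3) -> FluxEstimate:
    """Fick's-law flux from the near-interface concentration gradient.

    The gradient is the OLS slope through the first ``window`` points at
    z >= 0 (OLS rather than a two-point difference, for robustness to
    electrode noise).  Units: uM/um gradient x D_e in cm^2/s ->
    umol cm^-2 s^-1.
    """
    mask = profile.z >= 0
    idx = np.flatnonzero(mask)[:window]
    if idx.size < 2:
        raise ValueError("flux window needs at least 2 points at z >= 0")
    z_w, c_w = profile.z[idx], profile.C[idx]
    if np.ptp(z_w) == 0:
        raise ValueError("degenerate flux window: single depth")
    slope = stats.linregress(z_w, c_w).slope  # uM/um
    J = D_e * abs(slope) * _GRADIENT_TO_CGS
    return FluxEstimate(J=float(J), gradient=float(slope), window=tuple(int(i) for i in idx), D_e=D_e)


def surface_flux_closed_form(model: ReactionDiffusionModel) -> float:
    """Analytic interface flux of the first-order slab, umol cm^-2 s^-1.

    J = D_e * C0 * (-du/dzeta|0) / L_f with -du/dzeta|0 = phi*tanh(phi),
    equivalently C0 * sqrt(D_e*k1) * tanh(phi).
    """
    if model.kinetic_order != "first":
        raise ValueError("closed-form flux implemented for the first-order slab")
    c0 = model.C0 * UM_TO_UMOL_PER_CM3  # umol/cm3
    phi = model.phi
    return float(model.D_e * c0 * phi * np.tanh(phi) / model.L_f)


def solve_slab_parameters(
    flux: float, phi: float, D_e: float, C0: float
) -> tuple[float, float]:
    """Invert (J, phi) -> (k1, L_f) for the first-order slab.

    Given a target surface flux (umol cm^-2 s^-1), Thiele modulus,
    diffusivity (cm^2/s) and bulk O2 (uM), solve
    J = D_e*C0*phi*tanh(phi)/L_f for L_f, then k1 = phi^2*D_e/L_f^2.
    """
    if min(flux, phi, D_e, C0) <= 0:
        raise ValueError("flux, phi, D_e and C0 must be positive")
    c0 = C0 * UM_TO_UMOL_PER_CM3
    L_f = D_e * c0 * phi * np.tanh(phi) / flux
    k1 = phi**2 * D_e / L_f**2
    return float(k1), float(L_f)


def fit_profile(
    profile: Microprofile, order: str, L_f: float, D_e: float
) -> tuple[float, float, float]:
    """Least-squares fit of the dimensionless slab solution to a profile.

    The profile is normalised by C_bulk; only phi is identifiable from
    the shape, so L_f and D_e are explicit inputs and the rate constant
    is back-computed as k1 = phi^2 * D_e / L_f^2.

    Returns ``(k1, phi, rmse)`` with rmse in u units.
    """
    if profile.C_bulk <= 0:
        raise ValueError("C_bulk must be positive")
    if not np.any(profile.C > 0):
        raise ValueError("cannot fit an all-zero profile")
    if L_f <= 0 or D_e <= 0:
        raise ValueError("L_f and D_e must be positive")
    u_obs = profile.C / profile.C_bulk
    zeta = profile.z / (L_f * UM_PER_CM)
    if np.any(zeta > 1.0 + 1e-12):
        raise ValueError("profile extends beyond the slab thickness L_f")
    zeta = np.clip(zeta, 0.0, 1.0)

    def resid(log_phi: np.ndarray) -> np.ndarray:
        return dimensionless_profile(order, float(np.exp(log_phi[0])), zeta) - u_obs

    # Flat profiles have no consumption: phi = 0 exactly.
    if np.allclose(u_obs, u_obs[0]) and np.isclose(u_obs[0], 1.0, atol=1e-9):
        return 0.0, 0.0, float(np.sqrt(np.mean((u_obs - 1.0) ** 2)))

    sol = optimize.least_squares(resid, x0=[0.0], method="lm")
    phi = float(np.exp(sol.x[0]))
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    k1 = phi**2 * D_e / L_f**2
    return k1, phi, rmse


def penetration_depth(profile: Microprofile, detection_limit: float = 0.3) -> float | None:
    """Depth (um) where O2 first drops below the detection limit.

    Linear interpolation between the bracketing points; ``None`` if the
    profile never crosses the limit.
    """
    below = profile.C < detection_limit
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(profile.z[0])
    z0, z1 = profile.z[i - 1], profile.z[i]
    c0, c1 = profile.C[i - 1], profile.C[i]
    if c0 == c1:
        return float(z1)
    frac = (c0 - detection_limit) / (c0 - c1)
    return float(z0 + frac * (z1 - z0))
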