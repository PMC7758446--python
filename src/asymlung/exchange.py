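"""Species exchange between the airway/acinar tissue and the lumen.

The bronchial wall is a three-layer slab around the lumen: a liquid
lining (pure diffusive barrier), the epithelium (site of volumetric
production ``P`` and first-order consumption ``k_t``) and a
muscle/connective layer (consumption only).  The species concentration
is pinned to zero at the liquid--lumen interface and at the
tissue--blood interface (the blood is an infinite sink), which makes
the wall-to-lumen flux density time-independent.  The closed-form flux

    J_br = (P * dE / 2) * (dE + 2 dM) / (dmu + dE + dM + dmu/2 * Ha^2)

with the Hatta number ``Ha = (dE + dM) * sqrt(k_t / D_t)`` is validated
here against a brute-force planar diffusion--reaction boundary-value
solve (`wall_flux_bvp_oracle`).

In the acini, alveoli budding on the airway walls both consume the
species through the alveolar barrier (toward the blood, proportional to
the perfusion coefficient ``gamma``) and shrink the producing wall
surface; the net exchange density is affine in the local lumen
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .geometry import GeometryParams

__all__ = [
    "SpeciesParams",
    "WallLayers",
    "hatta_number",
    "wall_flux_density",
    "wall_flux_bvp_oracle",
    "airway_source",
    "acinar_flux_density",
    "acinar_flux_coefficients",
    "ppb_to_molar",
    "molar_to_ppb",
]

BODY_TEMPERATURE = 310.15  # K
ATMOSPHERIC_PRESSURE = 101325.0  # Pa
GAS_CONSTANT = 8.314462618  # J mol^-1 K^-1


def ppb_to_molar(x_ppb: np.ndarray | float) -> np.ndarray | float:
    """Molar fraction in ppb to mol m^-3 (ideal gas, 1 atm, 37 C)."""
    return x_ppb * 1e-9 * ATMOSPHERIC_PRESSURE / (GAS_CONSTANT * BODY_TEMPERATURE)


def molar_to_ppb(c: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`ppb_to_molar`."""
    return c * 1e9 * GAS_CONSTANT * BODY_TEMPERATURE / ATMOSPHERIC_PRESSURE


@dataclass(frozen=True)
class SpeciesParams:
    """Physicochemical parameters of the exchanged species (defaults: NO)."""

    tissue_diffusivity: float = 3.3e-9    # D_t, m^2 s^-1
    consumption_rate: float = 0.2         # k_t, s^-1 (first-order, in tissue)
    production_rate: float = 25e-6        # P, mol m^-3 s^-1 (epithelium)
    alveolar_transfer: float = 2e-3       # k_alv, m s^-1
    c_eq_ppb: float = 2.0                 # lumen concentration at blood equilibrium
    c_in_ppb: float = 0.0                 # inhaled concentration
    delta_mu: float = 10e-6               # reference liquid-layer thickness, m
    delta_e: float = 10e-6                # reference epithelium thickness, m
    delta_m: float = 30e-6                # reference muscle/tissue thickness, m

    def __post_init__(self) -> None:
        if self.tissue_diffusivity <= 0:
            raise ValueError("tissue diffusivity must be positive")
        for name in ("consumption_rate", "production_rate", "alveolar_transfer",
                     "c_eq_ppb", "c_in_ppb", "delta_mu", "delta_e", "delta_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def c_eq(self) -> float:
        return float(ppb_to_molar(self.c_eq_ppb))

    @property
    def c_in(self) -> float:
        return float(ppb_to_molar(self.c_in_ppb))


@dataclass(frozen=True)
class WallLayers:
    """Cross-sectional wall geometry of one airway."""

    lumen_radius: float
    delta_mu: float
    delta_e: float
    delta_m: float

    def __post_init__(self) -> None:
        if min(self.delta_mu, self.delta_e, self.delta_m) < 0 or self.lumen_radius < 0:
            raise ValueError("layer thicknesses and lumen radius must be non-negative")


def hatta_number(
    delta_e: np.ndarray | float,
    delta_m: np.ndarray | float,
    k_t: float,
    d_t: float,
) -> np.ndarray | float:
    """Hatta number (dE + dM) * sqrt(k_t / D_t).

    Ratio of the wall-consumption rate to the wall-diffusion rate; for
    Ha >> 1 most of the produced species is consumed before reaching
    the lumen.
    """
    if d_t <= 0:
        raise ValueError("tissue diffusivity must be positive")
    return (delta_e + delta_m) * np.sqrt(k_t / d_t)


def wall_flux_density(
    layers: WallLayers | None = None,
    sp: SpeciesParams | None = None,
    *,
    delta_mu: np.ndarray | float | None = None,
    delta_e: np.ndarray | float | None = None,
    delta_m: np.ndarray | float | None = None,
) -> np.ndarray | float:
    """Wall-to-lumen flux density J_br (mol m^-2 s^-1).

    Layer thicknesses default to ``layers``; passing the keyword arrays
    instead evaluates the closed form vectorized over airways.
    """
    sp = sp or SpeciesParams()
    if layers is not None:
        delta_mu, delta_e, delta_m = layers.delta_mu, layers.delta_e, layers.delta_m
    if delta_mu is None or delta_e is None or delta_m is None:
        raise ValueError("provide WallLayers or all three thickness arrays")
    total = np.asarray(delta_mu, dtype=float) + delta_e + delta_m
    if np.any(total <= 0):
        raise ValueError("wall flux undefined for an all-zero wall")
    ha2 = hatta_number(delta_e, delta_m, sp.consumption_rate, sp.tissue_diffusivity) ** 2
    num = sp.production_rate * np.asarray(delta_e, dtype=float) / 2.0 * (delta_e + 2.0 * delta_m)
    den = total + np.asarray(delta_mu, dtype=float) / 2.0 * ha2
    out = num / den
    return float(out) if np.isscalar(delta_e) or np.ndim(out) == 0 else out


def wall_flux_bvp_oracle(
    layers: WallLayers, sp: SpeciesParams, n_grid: int = 4000
) -> float:
    """Brute-force planar diffusion--reaction solve of the layered wall.

    Solves D_t c'' - k_t c + P*1[epithelium] = 0 on a uniform grid over
    liquid + epithelium + muscle (no consumption or production in the
    liquid), with c = 0 at the liquid--lumen and tissue--blood
    interfaces, and returns the flux magnitude D_t |c'| at the lumen
    side.  Second-order accurate; independent of the closed form it
    cross-checks.
    """
    if n_grid < 100:
        raise ValueError("n_grid too coarse for a trustworthy oracle")
    a, b, c = layers.delta_mu, layers.delta_e, layers.delta_m
    total = a + b + c
    if total <= 0:
        raise ValueError("wall flux undefined for an all-zero wall")
    x = np.linspace(0.0, total, n_grid + 1)
    h = x[1] - x[0]

    def overlap(lo: float, hi: float) -> np.ndarray:
        # fraction of each node's control interval inside [lo, hi]; keeps
        # the scheme second order when layer interfaces fall between nodes
        left = np.maximum(x - h / 2.0, lo)
        right = np.minimum(x + h / 2.0, hi)
        return np.clip(right - left, 0.0, None) / h

    k_node = sp.consumption_rate * overlap(a, total)
    src = sp.production_rate * overlap(a, a + b)
    d_t = sp.tissue_diffusivity
    n_i = n_grid - 1
    main = -2.0 * d_t / h**2 - k_node[1:-1]
    mat = scipy.sparse.diags(
        [np.full(n_i - 1, d_t / h**2), main, np.full(n_i - 1, d_t / h**2)],
        [-1, 0, 1],
        format="csc",
    )
    conc = scipy.sparse.linalg.spsolve(mat, -src[1:-1])
    conc = np.concatenate([[0.0], conc, [0.0]])
    # one-sided second-order derivative at the lumen interface
    flux = d_t * (-3.0 * conc[0] + 4.0 * conc[1] - conc[2]) / (2.0 * h)
    return float(abs(flux))


def airway_source(
    length: np.ndarray | float,
    diameter: np.ndarray | float,
    j_br: np.ndarray | float,
) -> np.ndarray | float:
    """Total wall delivery rate F = pi * L * D * J_br (mol s^-1)."""
    return np.pi * length * diameter * j_br


def _acinar_geometry_factors(geom: GeometryParams) -> tuple[np.ndarray, np.ndarray]:
    """Alveolar area ratio and residual wall fraction per acinar generation."""
    n_alv = np.asarray(geom.n_alv, dtype=float)
    area_ratio = n_alv * geom.d_alv**2 / (2.0 * geom.acinar_diameter * geom.acinar_length)
    wall_fraction = np.maximum(
        0.0, 1.0 - n_alv * geom.d_alv**2 / (4.0 * geom.acinar_diameter * geom.acinar_length)
    )
    return area_ratio, wall_fraction


def acinar_flux_coefficients(
    geom: GeometryParams, sp: SpeciesParams, gamma: np.ndarray | float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Affine decomposition J_a,m = slope_m * C + intercept_m, m = 1..7.

    ``gamma`` may be a scalar or an array broadcast against the 7
    generations (trailing axis).  The slope is non-positive
    (consumption) and proportional to gamma; the intercept carries the
    blood-equilibrium release and the residual wall production,
    evaluated with a liquid-free wall (healthy acini carry no liquid
    lining).
    """
    area_ratio, wall_fraction = _acinar_geometry_factors(geom)
    gamma = np.asarray(gamma, dtype=float)[..., None] if np.ndim(gamma) else gamma
    slope = -gamma * sp.alveolar_transfer * area_ratio
    j_wall = wall_flux_density(sp=sp, delta_mu=0.0, delta_e=sp.delta_e, delta_m=sp.delta_m)
    intercept = gamma * sp.alveolar_transfer * sp.c_eq * area_ratio + j_wall * wall_fraction
    return slope, intercept


def acinar_flux_density(
    m: int,
    concentration: float,
    gamma: float,
    geom: GeometryParams,
    sp: SpeciesParams,
) -> float:
    """Net exchange density J_a,m (mol m^-2 s^-1) in acinar generation m.

    Positive toward the lumen; the uptake term vanishes at the
    blood-equilibrium concentration and the production term vanishes on
    generations fully covered by alveolar openings.
    """
    if not 1 <= m <= 7:
        raise ValueError("acinar generation index m must be in 1..7")
    slope, intercept = acinar_flux_coefficients(geom, sp, gamma)
    return float(slope[m - 1] * concentration + intercept[m - 1])
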