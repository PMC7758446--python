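"""Quasi-steady 1D transport through the seven acinar generations.

Each acinar generation m holds 2**(m-1) identical cylindrical airways
(length L_a, diameter D_a), so the gas flow per airway halves at every
acinar bifurcation while the total cross-section doubles.  Per airway
the steady convection--diffusion balance reads

    +/- u_m dC/dz = D_g d^2C/dz^2 + (4 / D_a) J_a,m(C)

with u_m the mean velocity in generation m and J_a,m affine in C (see
:mod:`asymlung.exchange`).  Interfaces impose concentration continuity
and diffusive-flux conservation with the area doubling.  At the distal end of generation 7 two
closures are available: the default pins the gas to the
blood-equilibrium concentration (the alveolar sacs as a large,
well-perfused reservoir), the alternative closes the end with zero
diffusive flux.  The sac closure keeps the proximal gradient bounded
even when the wall uptake is switched off (perfusion-defect
scenarios), which a closed end cannot do.  The system is linear, so the
proximal concentration gradient is an affine map of the proximal
concentration,

    dC/dz|_{z=0} = a * C(0) + b,

which is the only piece of acinar information the bronchial transport
solver needs (it closes the distal boundary condition of every terminal
airway).  The per-generation solutions are composed in closed form
(scaled exponentials plus a particular term); two solves, at C(0) = 0
and C(0) = 1, yield (a, b) by superposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .airflow import GasProperties
from .exchange import SpeciesParams, acinar_flux_coefficients
from .geometry import GeometryParams

__all__ = ["AcinarLinking", "AcinarProfile", "build_linking", "build_linkings", "acinar_profile"]

N_GEN = 7
#: below this local Peclet/reaction scale the degenerate closed forms apply
_DEGENERATE = 1e-10


def _direction_sign(direction: str) -> float:
    if direction == "inspiration":
        return 1.0
    if direction == "expiration":
        return -1.0
    raise ValueError("direction must be 'inspiration' or 'expiration'")


@dataclass(frozen=True)
class AcinarLinking:
    """Affine proximal-gradient map of one acinus: dC/dz|0 = a*C(0) + b."""

    direction: str
    slope: float       # a, m^-1
    intercept: float   # b, mol m^-4
    gamma: float
    flow: float        # Q_a, m^3 s^-1

    def gradient(self, c_prox: float) -> float:
        return self.slope * c_prox + self.intercept


class _GenerationBasis:
    """Closed-form solution pieces of all 7 generations, batched over acini.

    Every array has shape (n, 7).  The general solution per generation
    is C(z) = c1*E1(z) + c2*E2(z) + Cp(z) with E scaled so that
    |E| <= 1 on [0, L_a] (exponents are referenced to the end where they
    would overflow).
    """

    def __init__(
        self,
        gammas: np.ndarray,
        flows: np.ndarray,
        geom: GeometryParams,
        sp: SpeciesParams,
        gas: GasProperties,
        direction: str,
        distal: str = "sac_equilibrium",
    ) -> None:
        if distal not in ("sac_equilibrium", "zero_flux"):
            raise ValueError("distal must be 'sac_equilibrium' or 'zero_flux'")
        self.distal = distal
        self.c_sac = sp.c_eq
        d = _direction_sign(direction)
        la, da, dg = geom.acinar_length, geom.acinar_diameter, gas.diffusivity
        m = np.arange(1, N_GEN + 1)
        u = 4.0 * (flows[:, None] / 2.0 ** (m - 1)) / (np.pi * da**2)  # (n, 7)
        s_m, q_m = acinar_flux_coefficients(geom, sp, gammas)  # (n,7) or (7,)
        s_m = np.broadcast_to(s_m, u.shape)
        q_m = np.broadcast_to(q_m, u.shape)

        # C'' + p C' + r C + w = 0
        p = -d * u / dg
        r = 4.0 * s_m / (da * dg)
        w = 4.0 * q_m / (da * dg)

        disc = np.sqrt(p**2 - 4.0 * r)  # r <= 0, always real
        lam1 = (-p - disc) / 2.0
        lam2 = (-p + disc) / 2.0

        self.degenerate = (np.abs(r) * la**2 < _DEGENERATE) & (np.abs(p) * la < _DEGENERATE)
        r_deg = np.abs(r) * la**2 < _DEGENERATE
        p_deg = np.abs(p) * la < _DEGENERATE

        ref1 = np.where(lam1 > 0, la, 0.0)
        ref2 = np.where(lam2 > 0, la, 0.0)
        # basis values/derivatives at z = 0 and z = L_a; degenerate -> {1, z}
        self.e1_0 = np.where(self.degenerate, 1.0, np.exp(lam1 * (0.0 - ref1)))
        self.e1_l = np.where(self.degenerate, 1.0, np.exp(lam1 * (la - ref1)))
        self.de1_0 = np.where(self.degenerate, 0.0, lam1 * self.e1_0)
        self.de1_l = np.where(self.degenerate, 0.0, lam1 * self.e1_l)
        self.e2_0 = np.where(self.degenerate, 0.0, np.exp(lam2 * (0.0 - ref2)))
        self.e2_l = np.where(self.degenerate, la, np.exp(lam2 * (la - ref2)))
        self.de2_0 = np.where(self.degenerate, 1.0, lam2 * self.e2_0)
        self.de2_l = np.where(self.degenerate, 1.0, lam2 * self.e2_l)

        with np.errstate(divide="ignore", invalid="ignore"):
            cp_const = -w / r            # consumption present
            cp_lin = -w / p              # pure convection of the source
        self.cp_0 = np.where(r_deg, 0.0, cp_const)
        self.cp_l = np.where(
            r_deg,
            np.where(p_deg, -w * la**2 / 2.0, cp_lin * la),
            cp_const,
        )
        self.dcp_0 = np.where(r_deg, np.where(p_deg, 0.0, cp_lin), 0.0)
        self.dcp_l = np.where(r_deg, np.where(p_deg, -w * la, cp_lin), 0.0)

        self.lam1, self.lam2, self.ref1, self.ref2 = lam1, lam2, ref1, ref2
        self.r_deg, self.p_deg, self.w = r_deg, p_deg, w
        self.length = la

    def assemble(self) -> tuple[np.ndarray, np.ndarray]:
        """Linear systems (n, 14, 14) with RHS columns for C(0) = 0 and 1."""
        n = self.e1_0.shape[0]
        mat = np.zeros((n, 2 * N_GEN, 2 * N_GEN))
        rhs = np.zeros((n, 2 * N_GEN, 2))
        # proximal concentration
        mat[:, 0, 0] = self.e1_0[:, 0]
        mat[:, 0, 1] = self.e2_0[:, 0]
        rhs[:, 0, 0] = -self.cp_0[:, 0]
        rhs[:, 0, 1] = 1.0 - self.cp_0[:, 0]
        row = 1
        for g in range(N_GEN - 1):
            c, n_ = 2 * g, 2 * (g + 1)
            # concentration continuity at the interface
            mat[:, row, c] = self.e1_l[:, g]
            mat[:, row, c + 1] = self.e2_l[:, g]
            mat[:, row, n_] = -self.e1_0[:, g + 1]
            mat[:, row, n_ + 1] = -self.e2_0[:, g + 1]
            rhs[:, row, :] = (self.cp_0[:, g + 1] - self.cp_l[:, g])[:, None]
            row += 1
            # diffusive-flux conservation with cross-section doubling
            mat[:, row, c] = self.de1_l[:, g]
            mat[:, row, c + 1] = self.de2_l[:, g]
            mat[:, row, n_] = -2.0 * self.de1_0[:, g + 1]
            mat[:, row, n_ + 1] = -2.0 * self.de2_0[:, g + 1]
            rhs[:, row, :] = (2.0 * self.dcp_0[:, g + 1] - self.dcp_l[:, g])[:, None]
            row += 1
        # distal closure of generation 7
        if self.distal == "zero_flux":
            mat[:, row, 2 * N_GEN - 2] = self.de1_l[:, -1]
            mat[:, row, 2 * N_GEN - 1] = self.de2_l[:, -1]
            rhs[:, row, :] = -self.dcp_l[:, -1][:, None]
        else:  # alveolar-sac reservoir at blood equilibrium
            mat[:, row, 2 * N_GEN - 2] = self.e1_l[:, -1]
            mat[:, row, 2 * N_GEN - 1] = self.e2_l[:, -1]
            rhs[:, row, :] = (self.c_sac - self.cp_l[:, -1])[:, None]
        return mat, rhs


def _equilibrated_solve(mat: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Batched linear solve with row/column equilibration.

    Rows mixing O(1) continuity entries with strongly damped exponential
    flux entries (high local Peclet, vanishing uptake) can make the raw
    system arbitrarily ill-scaled; scaling each row and column by its
    largest magnitude restores bounded condition numbers without
    changing the solution.
    """
    r_scale = np.max(np.abs(mat), axis=2, keepdims=True)
    r_scale[r_scale == 0.0] = 1.0
    mat = mat / r_scale
    c_scale = np.max(np.abs(mat), axis=1, keepdims=True)
    c_scale[c_scale == 0.0] = 1.0
    mat = mat / c_scale
    sol = np.linalg.solve(mat, rhs / r_scale)
    return sol / np.swapaxes(c_scale, 1, 2)


def build_linkings(
    gammas: np.ndarray,
    flows: np.ndarray,
    geom: GeometryParams,
    sp: SpeciesParams,
    gas: GasProperties,
    direction: str,
    distal: str = "sac_equilibrium",
) -> tuple[np.ndarray, np.ndarray]:
    """Affine linking maps (a, b) for a batch of acini.

    ``gammas`` and ``flows`` are one array entry per acinus; flows are
    magnitudes (the direction flag fixes the convection sign).  Returns
    arrays of slopes a (m^-1) and intercepts b (mol m^-4).
    """
    gammas = np.atleast_1d(np.asarray(gammas, dtype=float))
    flows = np.atleast_1d(np.asarray(flows, dtype=float))
    if np.any(flows < 0):
        raise ValueError("acinar flow magnitudes must be non-negative")
    basis = _GenerationBasis(gammas, flows, geom, sp, gas, direction, distal)
    mat, rhs = basis.assemble()
    coeff = _equilibrated_solve(mat, rhs)  # (n, 14, 2)
    grad = (
        coeff[:, 0, :] * basis.de1_0[:, 0, None]
        + coeff[:, 1, :] * basis.de2_0[:, 0, None]
        + basis.dcp_0[:, 0, None]
    )
    b = grad[:, 0]
    a = grad[:, 1] - grad[:, 0]
    return a, b


def build_linking(
    gamma: float,
    flow: float,
    geom: GeometryParams,
    sp: SpeciesParams,
    gas: GasProperties,
    direction: str,
    distal: str = "sac_equilibrium",
) -> AcinarLinking:
    """Affine linking map of a single acinus (see :func:`build_linkings`)."""
    a, b = build_linkings(np.array([gamma]), np.array([flow]), geom, sp, gas,
                          direction, distal)
    return AcinarLinking(direction, float(a[0]), float(b[0]), gamma, flow)


@dataclass
class AcinarProfile:
    """Closed-form concentration field C_m(z) of one acinus, m = 1..7."""

    c_prox: float
    direction: str
    _basis: _GenerationBasis
    _coeff: np.ndarray  # (14,)

    def concentration(self, m: int, z: np.ndarray | float) -> np.ndarray | float:
        """C (mol m^-3) at axial position z in generation m (z=0 proximal)."""
        b = self._basis
        g = m - 1
        z = np.asarray(z, dtype=float)
        c1, c2 = self._coeff[2 * g], self._coeff[2 * g + 1]
        if b.degenerate[0, g]:
            e1, e2 = np.ones_like(z), z
        else:
            e1 = np.exp(b.lam1[0, g] * (z - b.ref1[0, g]))
            e2 = np.exp(b.lam2[0, g] * (z - b.ref2[0, g]))
        if b.r_deg[0, g]:
            cp = -b.w[0, g] * z**2 / 2.0 if b.p_deg[0, g] else self._cp_lin(g) * z
        else:
            cp = np.full_like(z, b.cp_0[0, g])
        return c1 * e1 + c2 * e2 + cp

    def _cp_lin(self, g: int) -> float:
        b = self._basis
        return float(b.dcp_0[0, g])

    def gradient(self, m: int, z: np.ndarray | float) -> np.ndarray | float:
        """dC/dz (mol m^-4) at axial position z in generation m."""
        b = self._basis
        g = m - 1
        z = np.asarray(z, dtype=float)
        c1, c2 = self._coeff[2 * g], self._coeff[2 * g + 1]
        if b.degenerate[0, g]:
            de1, de2 = np.zeros_like(z), np.ones_like(z)
        else:
            de1 = b.lam1[0, g] * np.exp(b.lam1[0, g] * (z - b.ref1[0, g]))
            de2 = b.lam2[0, g] * np.exp(b.lam2[0, g] * (z - b.ref2[0, g]))
        if b.r_deg[0, g]:
            dcp = -b.w[0, g] * z if b.p_deg[0, g] else self._cp_lin(g)
        else:
            dcp = 0.0
        return c1 * de1 + c2 * de2 + dcp

    @property
    def proximal_gradient(self) -> float:
        return float(self.gradient(1, 0.0))


def acinar_profile(
    gamma: float,
    flow: float,
    geom: GeometryParams,
    sp: SpeciesParams,
    gas: GasProperties,
    direction: str,
    c_prox: float,
    distal: str = "sac_equilibrium",
) -> AcinarProfile:
    """Full per-generation concentration field for a given proximal value."""
    basis = _GenerationBasis(
        np.array([gamma]), np.array([flow]), geom, sp, gas, direction, distal
    )
    mat, rhs = basis.assemble()
    combined = (rhs[:, :, 0] + c_prox * (rhs[:, :, 1] - rhs[:, :, 0]))[:, :, None]
    coeff = _equilibrated_solve(mat, combined)[0, :, 0]
    return AcinarProfile(c_prox, direction, basis, coeff)
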