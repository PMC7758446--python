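"""Species transport in the lumen of the tracheobronchial tree.

Steady mode (exhaled-NO tests): per airway the quasi-steady 1D
convection--diffusion equation

    -/+ V dC/dz = D_g d^2C/dz^2 + S,      S = 4 J_br / D,

has the closed form C(z) = A + B e^{dVz/Dg} + (S/(dV)) z (d = +1
inspiration, -1 expiration; a quadratic branch covers V -> 0).  The two
coefficients per airway are fixed by the tracheal boundary condition,
concentration continuity and diffusive-flux conservation at every
bifurcation (cross-sections weighted by D^2), and the acinar linking
map at every terminal airway, yielding one sparse linear system of
size 2 * n_airw.  The exhaled fraction F_E_NO is the concentration at
the proximal end of the trachea at the end of a long expiration.

Unsteady mode: a conservative finite-volume discretization of the same
equation (first-order upwind convection, central diffusion, implicit
Euler) for time-dependent manoeuvres; the acinar linking closes the
terminal faces quasi-steadily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sparse
import scipy.sparse.linalg as sla

from .acinus import build_linkings
from .airflow import FlowSolution, GasProperties
from .exchange import SpeciesParams, molar_to_ppb, wall_flux_density
from .geometry import LungTree

__all__ = [
    "SteadyAirwaySolution",
    "ConcentrationField",
    "steady_airway_solution",
    "assemble_steady_system",
    "solve_steady",
    "solve_feno",
    "solve_unsteady",
    "global_balance_residual",
]

#: dimensionless Peclet below which the pure-diffusion branch applies
_V_DEGENERATE = 1e-8


def _direction_sign(direction: str) -> float:
    if direction == "inspiration":
        return 1.0
    if direction == "expiration":
        return -1.0
    raise ValueError("direction must be 'inspiration' or 'expiration'")


@dataclass(frozen=True)
class SteadyAirwaySolution:
    """Two-parameter closed-form family for one airway.

    ``C(z) = A + B * exp(lam * (z - ref)) + g(z)`` where the exponent is
    referenced to the end of the airway at which it is largest (so the
    stored basis never overflows, whatever the Peclet number) and g is
    the particular response to the constant wall source.
    """

    velocity: float
    length: float
    diffusivity: float
    source: float
    direction: str
    lam: float = field(init=False)
    ref: float = field(init=False)
    degenerate: bool = field(init=False)

    def __post_init__(self) -> None:
        d = _direction_sign(self.direction)
        peclet = self.velocity * self.length / self.diffusivity
        degenerate = abs(peclet) < _V_DEGENERATE
        lam = 0.0 if degenerate else d * self.velocity / self.diffusivity
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "ref", self.length if lam > 0 else 0.0)
        object.__setattr__(self, "degenerate", degenerate)

    def basis(self, z: np.ndarray | float) -> np.ndarray | float:
        return np.exp(self.lam * (np.asarray(z, dtype=float) - self.ref))

    def particular(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        if self.degenerate:
            return -self.source * z**2 / (2.0 * self.diffusivity)
        d = _direction_sign(self.direction)
        return self.source / (d * self.velocity) * z

    def particular_gradient(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        if self.degenerate:
            return -self.source * z / self.diffusivity
        d = _direction_sign(self.direction)
        return np.full_like(z, self.source / (d * self.velocity))

    def concentration(self, z, a: float, b: float):
        return a + b * self.basis(z) + self.particular(z)

    def gradient(self, z, a: float, b: float):
        return b * self.lam * self.basis(z) + self.particular_gradient(z)


def steady_airway_solution(
    velocity: float, length: float, diffusivity: float, source: float, direction: str
) -> SteadyAirwaySolution:
    """Closed-form steady solution family of one airway (see class docs)."""
    if length <= 0 or velocity < 0:
        raise ValueError("require L > 0 and V >= 0")
    return SteadyAirwaySolution(velocity, length, diffusivity, source, direction)


class _TreeBasis:
    """Vectorized closed-form pieces for every airway of a tree."""

    def __init__(
        self, tree: LungTree, velocity: np.ndarray, sources: np.ndarray,
        diffusivity: float, direction: str,
    ) -> None:
        d = _direction_sign(direction)
        length = tree.length
        peclet = velocity * length / diffusivity
        self.degenerate = peclet < _V_DEGENERATE
        lam = np.where(self.degenerate, 0.0, d * velocity / diffusivity)
        ref = np.where(lam > 0, length, 0.0)
        self.e0 = np.exp(lam * (0.0 - ref))
        self.el = np.exp(lam * (length - ref))
        self.de0 = lam * self.e0
        self.del_ = lam * self.el
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = sources / (d * velocity)
        self.g0 = np.zeros(tree.n_airw)
        self.gl = np.where(
            self.degenerate, -sources * length**2 / (2.0 * diffusivity), slope * length
        )
        self.dg0 = np.where(self.degenerate, 0.0, slope)
        self.dgl = np.where(self.degenerate, -sources * length / diffusivity, slope)
        self.lam, self.ref = lam, ref
        self.direction = direction
        self.diffusivity = diffusivity
        self.sources = sources


@dataclass
class ConcentrationField:
    """Steady per-airway closed-form concentration field with F_E_NO."""

    tree: LungTree
    direction: str
    coeff_a: np.ndarray
    coeff_b: np.ndarray
    _basis: _TreeBasis
    linking_slope: np.ndarray   # per terminal airway (tree terminal order)
    linking_intercept: np.ndarray
    tracheal_flow: float

    def concentration(self, airway: int, z: np.ndarray | float) -> np.ndarray | float:
        """C (mol m^-3) at axial position z of the given flat airway id."""
        b = self._basis
        z = np.asarray(z, dtype=float)
        expo = np.exp(b.lam[airway] * (z - b.ref[airway]))
        if b.degenerate[airway]:
            g = -b.sources[airway] * z**2 / (2.0 * b.diffusivity)
        else:
            g = b.dg0[airway] * z
        return self.coeff_a[airway] + self.coeff_b[airway] * expo + g

    def distal_concentrations(self) -> np.ndarray:
        b = self._basis
        return self.coeff_a + self.coeff_b * b.el + b.gl

    def proximal_concentrations(self) -> np.ndarray:
        b = self._basis
        return self.coeff_a + self.coeff_b * b.e0 + b.g0

    @property
    def feno_ppb(self) -> float:
        """Exhaled molar fraction: trachea-top concentration in ppb."""
        return float(molar_to_ppb(self.concentration(0, 0.0)))

    def generation_profile(self) -> pd.DataFrame:
        """Mean +/- sd of distal-end concentrations per generation (ppb).

        Reported on the clinical convention where the top of the trachea
        is generation 0; generation i >= 1 averages the distal ends of
        the internal generation-i airways (airways weighted equally).
        """
        distal = molar_to_ppb(self.distal_concentrations())
        rows = [(0, self.feno_ppb, 0.0)]
        for g in np.unique(self.tree.generation):
            sel = self.tree.generation == g
            rows.append((int(g), float(distal[sel].mean()), float(distal[sel].std())))
        return pd.DataFrame(rows, columns=["generation_index", "mean_ppb", "sd_ppb"])


def assemble_steady_system(
    tree: LungTree,
    flow: FlowSolution,
    sources: np.ndarray,
    linking_slope: np.ndarray,
    linking_intercept: np.ndarray,
    direction: str,
    c_in: float,
    diffusivity: float,
) -> tuple[sparse.csr_matrix, np.ndarray, _TreeBasis]:
    """Sparse linear system for the per-airway coefficients (A, B).

    Unknown ordering interleaves (A_k, B_k) at rows 2k, 2k+1 of the
    2*n_airw system.  Rows encode the tracheal boundary condition, two
    concentration-continuity and one flux-conservation row per
    bifurcation (cross-sections weighted by D^2), and the acinar
    linking condition at every terminal airway:
    D^2 C'(L) = 2 (phi D_a)^2 (a C(L) + b).
    """
    n = tree.n_airw
    basis = _TreeBasis(tree, flow.velocity, sources, diffusivity, direction)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    rhs = np.zeros(2 * n)

    def add(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.asarray(v, dtype=float))

    # trachea proximal condition (row 0)
    if direction == "inspiration":
        add([0, 0], [0, 1], [1.0, basis.e0[0]])
        rhs[0] = c_in - basis.g0[0]
    else:  # no axial diffusion at the mouth
        add([0], [1], [basis.de0[0]])
        rhs[0] = -basis.dg0[0]

    inner = np.flatnonzero(~tree.terminal)
    term = tree.terminal_ids
    cm, cM = tree.child_minor[inner], tree.child_major[inner]
    # row layout: 3 rows per internal airway then 1 per terminal
    r0 = 1 + 3 * np.arange(inner.size)

    for child, shift in ((cm, 0), (cM, 1)):
        r = r0 + shift
        # C_parent(L) - C_child(0) = g_child(0) - g_parent(L)
        add(r, 2 * inner, np.ones(inner.size))
        add(r, 2 * inner + 1, basis.el[inner])
        add(r, 2 * child, -np.ones(inner.size))
        add(r, 2 * child + 1, -basis.e0[child])
        rhs[r] = basis.g0[child] - basis.gl[inner]
    # diffusive-flux conservation, D^2-weighted
    r = r0 + 2
    d2p = tree.diameter[inner] ** 2
    d2m = tree.diameter[cm] ** 2
    d2M = tree.diameter[cM] ** 2
    add(r, 2 * inner + 1, d2p * basis.del_[inner])
    add(r, 2 * cm + 1, -d2m * basis.de0[cm])
    add(r, 2 * cM + 1, -d2M * basis.de0[cM])
    rhs[r] = d2m * basis.dg0[cm] + d2M * basis.dg0[cM] - d2p * basis.dgl[inner]

    # terminal rows: acinar linking boundary condition
    rt = 1 + 3 * inner.size + np.arange(term.size)
    d2t = tree.diameter[term] ** 2
    area_acinus = 2.0 * (tree.phi[term] * tree.params.acinar_diameter) ** 2
    a_lnk, b_lnk = linking_slope, linking_intercept
    add(rt, 2 * term, -area_acinus * a_lnk)
    add(rt, 2 * term + 1, d2t * basis.del_[term] - area_acinus * a_lnk * basis.el[term])
    rhs[rt] = area_acinus * (a_lnk * basis.gl[term] + b_lnk) - d2t * basis.dgl[term]

    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(2 * n, 2 * n),
    ).tocsr()
    return mat, rhs, basis


def solve_steady(
    tree: LungTree,
    flow: FlowSolution,
    sp: SpeciesParams,
    gas: GasProperties,
    direction: str,
    distal: str = "sac_equilibrium",
) -> ConcentrationField:
    """Steady concentration field for a solved flow state.

    Wall sources come from the per-airway layer thicknesses; every
    terminal airway is closed by the affine acinar linking map built at
    half its flow (two acini in parallel) and its perfusion
    coefficient.
    """
    j_br = wall_flux_density(
        sp=sp, delta_mu=tree.delta_mu, delta_e=tree.delta_e, delta_m=tree.delta_m
    )
    sources = 4.0 * j_br / tree.diameter
    term = tree.terminal_ids
    a_lnk, b_lnk = build_linkings(
        tree.gamma[term], flow.flow[term] / 2.0, tree.params, sp, gas, direction,
        distal,
    )
    mat, rhs, basis = assemble_steady_system(
        tree, flow, sources, a_lnk, b_lnk, direction, sp.c_in, gas.diffusivity
    )
    sol = sla.spsolve(mat.tocsc(), rhs)
    return ConcentrationField(
        tree=tree,
        direction=direction,
        coeff_a=sol[0::2],
        coeff_b=sol[1::2],
        _basis=basis,
        linking_slope=a_lnk,
        linking_intercept=b_lnk,
        tracheal_flow=flow.tracheal_flow,
    )


def solve_feno(
    tree: LungTree,
    flow: FlowSolution,
    sp: SpeciesParams,
    gas: GasProperties,
    distal: str = "sac_equilibrium",
) -> ConcentrationField:
    """Steady expiration solve; ``.feno_ppb`` is the exhaled NO fraction.

    Valid for the standard slow-expiration manoeuvre (about 10 s at
    constant flow), for which the lumen profile has reached steady
    state.
    """
    return solve_steady(tree, flow, sp, gas, "expiration", distal)


def global_balance_residual(
    field: ConcentrationField, tree: LungTree, flow: FlowSolution, sp: SpeciesParams,
) -> float:
    """Relative steady NO balance error of an expiration field.

    Convective outflow at the trachea must equal total wall production
    plus the net convective + diffusive supply through the terminal
    faces from the acini.
    """
    if field.direction != "expiration":
        raise ValueError("balance audit is defined for expiration fields")
    j_br = wall_flux_density(
        sp=sp, delta_mu=tree.delta_mu, delta_e=tree.delta_e, delta_m=tree.delta_m
    )
    wall = float(np.sum(np.pi * tree.length * tree.diameter * j_br))
    term = tree.terminal_ids
    c_l = field.distal_concentrations()[term]
    grad = field.linking_slope * c_l + field.linking_intercept
    area_eff = np.pi / 2.0 * (tree.phi[term] * tree.params.acinar_diameter) ** 2
    acinar = float(
        np.sum(flow.flow[term] * c_l + field._basis.diffusivity * area_eff * grad)
    )
    out = flow.tracheal_flow * field.concentration(0, 0.0)
    return abs(out - (wall + acinar)) / abs(out)


# ---------------------------------------------------------------------------
# unsteady finite-volume solver


@dataclass
class UnsteadyResult:
    """Mouth concentration time series plus the final cell-centred field."""

    times: np.ndarray
    mouth_ppb: np.ndarray
    concentrations: np.ndarray      # final field, all cells
    cell_offsets: np.ndarray        # per-airway slice starts into the field
    cells_per_airway: np.ndarray
    tree: LungTree

    def airway_cells(self, airway: int) -> np.ndarray:
        lo = self.cell_offsets[airway]
        return self.concentrations[lo: lo + self.cells_per_airway[airway]]

    def cell_centres(self, airway: int) -> np.ndarray:
        n = self.cells_per_airway[airway]
        h = self.tree.length[airway] / n
        return (np.arange(n) + 0.5) * h


def _fvm_operator(
    tree: LungTree,
    flow: FlowSolution,
    sp: SpeciesParams,
    gas: GasProperties,
    direction: str,
    cells_per_airway: np.ndarray,
    distal: str = "sac_equilibrium",
) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray, np.ndarray]:
    """Build dC/dt = A C + r for the whole tree (linear, constant flow)."""
    d = _direction_sign(direction)
    dg = gas.diffusivity
    n_cells = int(cells_per_airway.sum())
    offsets = np.concatenate([[0], np.cumsum(cells_per_airway)[:-1]])
    area = np.pi * tree.diameter**2 / 4.0
    h = tree.length / cells_per_airway
    vol = area * h
    j_br = wall_flux_density(
        sp=sp, delta_mu=tree.delta_mu, delta_e=tree.delta_e, delta_m=tree.delta_m
    )
    src = 4.0 * j_br / tree.diameter  # mol m^-3 s^-1 per cell

    term = tree.terminal_ids
    a_lnk, b_lnk = build_linkings(
        tree.gamma[term], flow.flow[term] / 2.0, tree.params, sp, gas, direction,
        distal,
    )
    slope_of = np.zeros(tree.n_airw)
    icpt_of = np.zeros(tree.n_airw)
    slope_of[term], icpt_of[term] = a_lnk, b_lnk

    mat = sparse.lil_matrix((n_cells, n_cells))
    rvec = np.zeros(n_cells)

    def couple(i, j, f_ij):
        """Add the exchange 'flux f_ij * (C_j - C_i)'-style terms."""
        mat[i, i] -= f_ij / vol_i_cache[i]
        mat[i, j] += f_ij / vol_i_cache[i]
        mat[j, j] -= f_ij / vol_i_cache[j]
        mat[j, i] += f_ij / vol_i_cache[j]

    vol_i_cache = np.concatenate(
        [np.full(cells_per_airway[k], vol[k]) for k in range(tree.n_airw)]
    )

    for k in range(tree.n_airw):
        lo, nk, hk = offsets[k], cells_per_airway[k], h[k]
        q, ak = flow.flow[k], area[k]
        cells = lo + np.arange(nk)
        rvec[cells] += src[k]
        # internal faces (signed flow w = d*q; upwind concentration)
        w = d * q
        for f in range(nk - 1):
            i, j = lo + f, lo + f + 1  # i proximal of j
            couple(i, j, dg * ak / hk)
            up = i if w > 0 else j
            mat[i, up] -= w / vol[k]
            mat[j, up] += w / vol[k]
        # proximal boundary of the trachea
        if k == 0:
            i = lo
            if direction == "inspiration":
                # convective inflow at C_in; diffusive with boundary value C_in
                rvec[i] += q * sp.c_in / vol[k]
                mat[i, i] -= dg * ak / (hk / 2.0) / vol[k]
                rvec[i] += dg * ak / (hk / 2.0) * sp.c_in / vol[k]
            else:
                # convective outflow, no axial diffusion at the mouth
                mat[i, i] -= q / vol[k]
        # distal end
        if tree.terminal[k]:
            i = lo + nk - 1
            area_eff = np.pi / 2.0 * (tree.phi[k] * tree.params.acinar_diameter) ** 2
            # diffusive exchange with the acinus via the linking map
            mat[i, i] += dg * area_eff * slope_of[k] / vol[k]
            rvec[i] += dg * area_eff * icpt_of[k] / vol[k]
            # convection through the distal face; the face concentration is
            # continuous with the acinus, approximated by the last cell
            if d > 0:
                mat[i, i] -= q / vol[k]   # outflow into the acinus
            else:
                mat[i, i] += q / vol[k]   # inflow from the acinus at C_face
    # junction faces
    for k in np.flatnonzero(~tree.terminal):
        ip = offsets[k] + cells_per_airway[k] - 1
        for child in (tree.child_minor[k], tree.child_major[k]):
            ic = offsets[child]
            qc = flow.flow[child]
            dist = (h[k] + h[child]) / 2.0
            diff = dg * area[child] / dist
            couple(ip, ic, diff)
            up = ip if d > 0 else ic
            mat[ip, up] -= d * qc / vol[k]
            mat[ic, up] += d * qc / vol[child]
    return mat.tocsr(), rvec, offsets, cells_per_airway


def solve_unsteady(
    tree: LungTree,
    flow: FlowSolution,
    sp: SpeciesParams,
    gas: GasProperties,
    *,
    direction: str = "expiration",
    t_end: float,
    dt: float = 0.01,
    cells_per_airway: np.ndarray | None = None,
    initial: np.ndarray | float | None = None,
    distal: str = "sac_equilibrium",
) -> UnsteadyResult:
    """Implicit-Euler finite-volume integration at constant flow.

    ``initial`` is a uniform concentration (mol m^-3) or a full cell
    array; by default the field starts at the inhaled concentration.
    The default grid puts ``max(4, ceil(L / (D/2)))`` cells in each
    airway.
    """
    if cells_per_airway is None:
        cells_per_airway = np.maximum(
            4, np.ceil(tree.length / (tree.diameter / 2.0)).astype(int)
        )
    cells_per_airway = np.asarray(cells_per_airway, dtype=int)
    op, rvec, offsets, cpa = _fvm_operator(tree, flow, sp, gas, direction,
                                            cells_per_airway, distal)
    n_cells = op.shape[0]
    if initial is None:
        c = np.full(n_cells, sp.c_in)
    elif np.ndim(initial) == 0:
        c = np.full(n_cells, float(initial))
    else:
        c = np.asarray(initial, dtype=float).copy()
        if c.size != n_cells:
            raise ValueError("initial field size does not match the grid")
    n_steps = int(np.ceil(t_end / dt))
    lhs = (sparse.identity(n_cells, format="csc") - dt * op.tocsc())
    solver = sla.splu(lhs)
    times = np.empty(n_steps + 1)
    mouth = np.empty(n_steps + 1)
    times[0], mouth[0] = 0.0, molar_to_ppb(c[0])
    for step in range(1, n_steps + 1):
        c = solver.solve(c + dt * rvec)
        if not np.all(np.isfinite(c)):
            raise RuntimeError("unsteady solve produced non-finite concentrations")
        times[step] = step * dt
        mouth[step] = molar_to_ppb(c[0])
    return UnsteadyResult(times, mouth, c, offsets, cpa, tree)
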