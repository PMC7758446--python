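"""Quasi-static airflow distribution in the airway tree.

The flow problem is posed as a resistive network (electrical analogy):
every airway carries a Poiseuille resistance multiplied by an
entrance-flow correction factor Z >= 1 that grows with the Reynolds
number (Pedley-type correction for non-established flow), and every
terminal airway sees the resistance of its two downstream acini in
parallel, scaled by the acinar reduction factor phi as 1/phi**3.
Because Z depends on the flow, the network is nonlinear and is solved
by a damped fixed-point iteration: resistances from the current flows,
subtree resistances leaf-to-root, then the flow redistributed root-to-
leaf at each bifurcation inversely to the downstream branch resistance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import LungTree

__all__ = [
    "GasProperties",
    "FlowSolution",
    "poiseuille_resistance",
    "acinus_resistance",
    "acinus_series_coefficient",
    "z_factor",
    "subtree_resistances",
    "solve_flow",
    "peclet_numbers",
]

#: Pedley entrance-flow constant
PEDLEY_C = 1.85


@dataclass(frozen=True)
class GasProperties:
    """Carrier-gas properties (defaults: air at body conditions, NO tracer)."""

    density: float = 1.14          # kg m^-3
    kinematic_viscosity: float = 1.67e-5  # m^2 s^-1
    diffusivity: float = 2.2e-5    # m^2 s^-1, species in the lumen gas

    def __post_init__(self) -> None:
        if min(self.density, self.kinematic_viscosity, self.diffusivity) <= 0:
            raise ValueError("gas properties must be positive")


@dataclass
class FlowSolution:
    """Per-airway flow state plus global diagnostics of the network solve."""

    flow: np.ndarray        # Q_ij, m^3 s^-1 (magnitude; direction is global)
    velocity: np.ndarray    # mean axial velocity, m s^-1
    reynolds: np.ndarray
    z: np.ndarray           # entrance-flow correction factor, >= 1
    resistance: np.ndarray  # Z-corrected airway resistance, Pa s m^-3
    subtree_resistance: np.ndarray
    tracheal_flow: float
    pressure_drop: float    # Pa, trachea inlet to alveoli
    direction: str
    iterations: int
    residual: float


def poiseuille_resistance(
    diameter: np.ndarray | float, length: np.ndarray | float, gas: GasProperties
) -> np.ndarray | float:
    """Fully developed laminar resistance 128*rho*nu*L/(pi*D^4)."""
    return 128.0 * gas.density * gas.kinematic_viscosity * length / (np.pi * diameter**4)


def acinus_series_coefficient(n_generations: int = 7) -> float:
    """Series coefficient of the acinar resistance, sum of 128/2**(m-1)."""
    return float(sum(128.0 / 2 ** (m - 1) for m in range(1, n_generations + 1)))


def acinus_resistance(gas: GasProperties, acinar_length: float, acinar_diameter: float) -> float:
    """Poiseuille resistance of one 7-generation acinus.

    Each acinar generation doubles the number of parallel identical
    airways, so the series sum is 128 * (1 + 1/2 + ... + 1/64) = 254
    times the single-airway prefactor.
    """
    return (
        acinus_series_coefficient()
        * gas.density * gas.kinematic_viscosity * acinar_length
        / (np.pi * acinar_diameter**4)
    )


def z_factor(
    reynolds: np.ndarray | float,
    diameter: np.ndarray | float,
    length: np.ndarray | float,
    c_p: float = PEDLEY_C,
) -> np.ndarray | float:
    """Entrance-flow resistance correction, floored at unity.

    Z = max(1, c_p/(4*sqrt(2)) * sqrt(Re * D / L)); continuous and
    non-decreasing in Re.
    """
    z = c_p / (4.0 * np.sqrt(2.0)) * np.sqrt(np.maximum(reynolds, 0.0) * diameter / length)
    return np.maximum(1.0, z)


def subtree_resistances(
    tree: LungTree, resistance: np.ndarray, r_acinus: float
) -> np.ndarray:
    """Downstream (peripheral) resistance of every airway, leaf-to-root.

    Terminals see their two acini in parallel scaled by phi**-3;
    intermediate airways combine their two daughter branches in
    parallel, each branch being the daughter's own resistance in series
    with its subtree resistance.
    """
    if np.any(tree.phi[tree.terminal] <= 0):
        raise ValueError("phi must be positive on terminal airways")
    r_sub = np.zeros(tree.n_airw)
    term = tree.terminal
    r_sub[term] = r_acinus / (2.0 * tree.phi[term] ** 3)
    # BFS storage: iterating ids in reverse visits children before parents
    cm, cM = tree.child_minor, tree.child_major
    inner = np.flatnonzero(~term)[::-1]
    for k in inner:
        b1 = resistance[cm[k]] + r_sub[cm[k]]
        b2 = resistance[cM[k]] + r_sub[cM[k]]
        r_sub[k] = b1 * b2 / (b1 + b2)
    return r_sub


def _distribute_flow(
    tree: LungTree, resistance: np.ndarray, r_sub: np.ndarray, q_root: float
) -> np.ndarray:
    """Split the tracheal flow at every bifurcation, root-to-leaf.

    The split is inversely proportional to the total downstream branch
    resistance, which conserves flow exactly at every bifurcation.
    """
    q = np.zeros(tree.n_airw)
    q[0] = q_root
    cm, cM = tree.child_minor, tree.child_major
    for k in np.flatnonzero(~tree.terminal):
        b1 = resistance[cm[k]] + r_sub[cm[k]]
        b2 = resistance[cM[k]] + r_sub[cM[k]]
        q[cm[k]] = q[k] * b2 / (b1 + b2)
        q[cM[k]] = q[k] - q[cm[k]]
    return q


def solve_flow(
    tree: LungTree,
    gas: GasProperties,
    *,
    tracheal_flow: float | None = None,
    pressure_drop: float | None = None,
    direction: str = "inspiration",
    tol: float = 1e-8,
    max_iter: int = 200,
    relaxation: float = 0.5,
) -> FlowSolution:
    """Solve the nonlinear flow distribution for a flow or pressure drive.

    Exactly one of ``tracheal_flow`` (m^3/s) and ``pressure_drop`` (Pa)
    must be given.  Expiration uses the same resistances with the flow
    direction reversed (quasi-static, no inertance), so only the
    transport solvers distinguish the two directions; here the flow
    magnitudes coincide.
    """
    if (tracheal_flow is None) == (pressure_drop is None):
        raise ValueError("give exactly one of tracheal_flow or pressure_drop")
    if direction not in ("inspiration", "expiration"):
        raise ValueError("direction must be 'inspiration' or 'expiration'")
    drive = tracheal_flow if tracheal_flow is not None else pressure_drop
    if drive is None or drive <= 0:
        raise ValueError("drive magnitude must be positive")

    p = tree.params
    r_acinus = acinus_resistance(gas, p.acinar_length, p.acinar_diameter)
    r_poiseuille = poiseuille_resistance(tree.diameter, tree.length, gas)
    area = np.pi * tree.diameter**2 / 4.0

    z = np.ones(tree.n_airw)
    q = np.zeros(tree.n_airw)
    residual = np.inf
    for iteration in range(1, max_iter + 1):
        resistance = z * r_poiseuille
        r_sub = subtree_resistances(tree, resistance, r_acinus)
        if pressure_drop is not None:
            q_root = pressure_drop / (resistance[0] + r_sub[0])
        else:
            q_root = tracheal_flow
        q_new = _distribute_flow(tree, resistance, r_sub, q_root)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(q_new - q) / np.maximum(np.abs(q_new), 1e-300)
        residual = float(np.max(rel)) if q.any() else np.inf
        q = q_new
        velocity = q / area
        reynolds = velocity * tree.diameter / gas.kinematic_viscosity
        z_new = z_factor(reynolds, tree.diameter, tree.length)
        if residual < tol:
            # keep the z that produced q so flows and resistances are
            # exactly consistent (path-independent pressure drops)
            break
        z = relaxation * z_new + (1.0 - relaxation) * z
    else:
        raise RuntimeError(
            f"flow solve did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})"
        )

    resistance = z * r_poiseuille
    r_sub = subtree_resistances(tree, resistance, r_acinus)
    return FlowSolution(
        flow=q,
        velocity=q / area,
        reynolds=q / area * tree.diameter / gas.kinematic_viscosity,
        z=z,
        resistance=resistance,
        subtree_resistance=r_sub,
        tracheal_flow=float(q[0]),
        pressure_drop=float(q[0] * (resistance[0] + r_sub[0])),
        direction=direction,
        iterations=iteration,
        residual=residual,
    )


def peclet_numbers(tree: LungTree, flow: FlowSolution, diffusivity: float) -> np.ndarray:
    """Axial Peclet number V*L/D_g of every airway."""
    return flow.velocity * tree.length / diffusivity
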