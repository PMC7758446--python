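"""Derived metrics and disease-scenario orchestration.

Covers the convective gas-delivery metrics (delivery time and supply
ratio of each acinus), the canonical exhaled-NO alteration scenarios
(intra-acinar narrowing, pre-acinar narrowing by muscle contraction or
liquid accumulation, perfusion defects), the COPD forced-expiration
experiment and the flow--pressure characteristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .airflow import FlowSolution, GasProperties, solve_flow
from .exchange import SpeciesParams
from .geometry import (
    GeometryParams,
    LungTree,
    apply_acinar_alteration,
    apply_lumen_alteration,
    generate_tree,
    select_airways,
)
from .transport import ConcentrationField, solve_feno

__all__ = [
    "DeliveryMetrics",
    "Alteration",
    "ScenarioSpec",
    "canonical_scenarios",
    "delivery_metrics",
    "apply_scenario",
    "run_no_scenario",
    "copd_fev1",
    "flow_pressure_curve",
    "fixture_tree",
]


@dataclass
class DeliveryMetrics:
    """Convective delivery statistics over the terminal airways.

    ``delivery_time`` is the inspiration time left for filling an acinus
    after the gas has crossed the upper-airway cavities and transited
    the tree (clamped at zero); ``supply_ratio`` compares the amount of
    fresh gas an acinus receives with the uniform, zero-transit ideal.
    """

    transit_time: np.ndarray
    delivery_time: np.ndarray
    supply_ratio: np.ndarray
    inspiration_time: float
    cavity_time: float
    cavity_volume: float
    terminal_ids: np.ndarray


def delivery_metrics(
    tree: LungTree,
    flow: FlowSolution,
    t_ins: float = 2.0,
    cavity_volume: float | None = None,
) -> DeliveryMetrics:
    """Per-acinus delivery time and gas supply ratio at constant inspiration."""
    if flow.tracheal_flow <= 0:
        raise ValueError("delivery metrics need a positive tracheal flow")
    v_cav = tree.params.cavity_volume if cavity_volume is None else cavity_volume
    t_cav = v_cav / flow.tracheal_flow
    residence = tree.length / flow.velocity
    # cumulative transit along the root path (parents precede children)
    t_cum = np.zeros(tree.n_airw)
    for k in range(tree.n_airw):
        p = tree.parent[k]
        t_cum[k] = residence[k] + (t_cum[p] if p >= 0 else 0.0)
    term = tree.terminal_ids
    t_trans = t_cum[term]
    t_del = np.maximum(0.0, t_ins - (t_cav + t_trans))
    omega = (
        flow.flow[term] * t_del
        / (flow.tracheal_flow / term.size * (t_ins - t_cav))
    )
    return DeliveryMetrics(t_trans, t_del, omega, t_ins, t_cav, v_cav, term)


@dataclass(frozen=True)
class Alteration:
    """One alteration step: a selection plus a lumen or acinar action."""

    select: dict
    beta: float | None = None
    mode: str | None = None       # 'muscle' | 'liquid' for lumen alterations
    phi: float | None = None
    gamma: float | None = None

    def apply(self, tree: LungTree) -> LungTree:
        ids = select_airways(tree, self.select)
        if self.beta is not None:
            tree = apply_lumen_alteration(tree, ids, self.beta, self.mode)
        if self.phi is not None or self.gamma is not None:
            tree = apply_acinar_alteration(tree, ids, phi=self.phi, gamma=self.gamma)
        return tree


@dataclass(frozen=True)
class ScenarioSpec:
    """A replayable scenario: labelled alterations plus solver settings."""

    label: str
    alterations: tuple[Alteration, ...]
    tracheal_flow: float = 50e-6
    production_multiplier: float = 1.0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "tracheal_flow": self.tracheal_flow,
            "production_multiplier": self.production_multiplier,
            "alterations": [
                {k: v for k, v in vars(a).items() if v is not None}
                for a in self.alterations
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        alts = tuple(Alteration(**a) for a in d.get("alterations", []))
        return cls(
            label=d["label"],
            alterations=alts,
            tracheal_flow=d.get("tracheal_flow", 50e-6),
            production_multiplier=d.get("production_multiplier", 1.0),
        )


def _extreme(which: str, fraction: float = 0.5) -> dict:
    return {"kind": "terminal_extreme", "fraction": fraction, "which": which}


#: diameter reduced by 65% -> area reduction beta = 1 - 0.35**2
_BETA_65 = 1.0 - 0.35**2


def canonical_scenarios() -> dict[str, ScenarioSpec]:
    """The six bundled unhealthy-lung scenarios (50 ml/s expiration).

    * ``intra_acinar_near`` / ``intra_acinar_far``: half the acini
      (nearest/farthest from the trachea) shrunk to 10% of their linear
      size (phi = 0.1).
    * ``preacinar_muscle`` / ``preacinar_liquid``: the farthest half of
      the terminal airways plus their three generations of parents
      narrowed by 65% in diameter, by smooth-muscle contraction or by
      liquid accumulation.
    * ``perfusion_mild_near`` / ``perfusion_severe_far``: perfusion
      coefficient gamma reduced to 0.7 on the nearest half, or to 1e-6
      on the farthest half, of the acini.
    """
    far_plus_parents = {"kind": "ancestors", "of": _extreme("farthest"), "k": 3,
                        "include_base": True}
    return {
        "intra_acinar_near": ScenarioSpec(
            "intra_acinar_near", (Alteration(_extreme("nearest"), phi=0.1),)),
        "intra_acinar_far": ScenarioSpec(
            "intra_acinar_far", (Alteration(_extreme("farthest"), phi=0.1),)),
        "preacinar_muscle": ScenarioSpec(
            "preacinar_muscle", (Alteration(far_plus_parents, beta=_BETA_65, mode="muscle"),)),
        "preacinar_liquid": ScenarioSpec(
            "preacinar_liquid", (Alteration(far_plus_parents, beta=_BETA_65, mode="liquid"),)),
        "perfusion_mild_near": ScenarioSpec(
            "perfusion_mild_near", (Alteration(_extreme("nearest"), gamma=0.7),)),
        "perfusion_severe_far": ScenarioSpec(
            "perfusion_severe_far", (Alteration(_extreme("farthest"), gamma=1e-6),)),
    }


def apply_scenario(tree: LungTree, spec: ScenarioSpec) -> LungTree:
    """Apply all alteration steps of a scenario to a copy of the tree."""
    for alteration in spec.alterations:
        tree = alteration.apply(tree)
    return tree


def run_no_scenario(
    tree: LungTree,
    spec: ScenarioSpec,
    sp: SpeciesParams | None = None,
    gas: GasProperties | None = None,
    baseline: ConcentrationField | None = None,
) -> dict:
    """Exhaled-NO change of a scenario against the paired healthy baseline.

    The baseline is computed on the identical geometry (same seed) at
    the same expiratory flow, so the null scenario reports exactly zero
    change.  Returns the baseline and altered F_E_NO (ppb), the
    relative change in percent, and the per-generation profile of the
    altered lungs.
    """
    sp = sp or SpeciesParams()
    gas = gas or GasProperties()
    if baseline is None:
        flow0 = solve_flow(tree, gas, tracheal_flow=spec.tracheal_flow,
                           direction="expiration")
        baseline = solve_feno(tree, flow0, sp, gas)
    altered = apply_scenario(tree, spec)
    sp_run = sp
    if spec.production_multiplier != 1.0:
        from dataclasses import replace
        sp_run = replace(sp, production_rate=sp.production_rate * spec.production_multiplier)
    flow1 = solve_flow(altered, gas, tracheal_flow=spec.tracheal_flow,
                       direction="expiration")
    result = solve_feno(altered, flow1, sp_run, gas)
    base_feno = baseline.feno_ppb
    return {
        "label": spec.label,
        "feno_baseline_ppb": base_feno,
        "feno_ppb": result.feno_ppb,
        "delta_feno_pct": 100.0 * (result.feno_ppb - base_feno) / base_feno,
        "profile": result.generation_profile(),
        "field": result,
    }


def copd_fev1(
    tree: LungTree,
    fsad_percent: float,
    emph_percent: float,
    pressure_drop: float = 250.0,
    seed: int = 0,
    gas: GasProperties | None = None,
) -> float:
    """Forced expiratory flow relative to healthy, in percent.

    Small-airway disease narrows a random ``fsad_percent`` of the small
    airways (D < 2 mm) by 99% of their lumen area; emphysema blocks a
    random ``emph_percent`` of the acini (phi = 0.01).  Both expiration
    solves are pressure-driven at the same alveolar overpressure.
    """
    if not (0 <= fsad_percent <= 100 and 0 <= emph_percent <= 100):
        raise ValueError("percentages must be within [0, 100]")
    gas = gas or GasProperties()
    healthy = solve_flow(tree, gas, pressure_drop=pressure_drop, direction="expiration")
    altered = tree
    if fsad_percent > 0:
        small = {"kind": "random_fraction", "fraction": fsad_percent / 100.0,
                 "seed": seed, "small_airways_below": 2e-3}
        altered = apply_lumen_alteration(
            altered, select_airways(altered, small), beta=0.99, mode="muscle")
    if emph_percent > 0:
        acini = {"kind": "random_fraction", "fraction": emph_percent / 100.0,
                 "seed": seed + 1}
        altered = apply_acinar_alteration(
            altered, select_airways(altered, acini), phi=0.01)
    diseased = solve_flow(altered, gas, pressure_drop=pressure_drop, direction="expiration")
    return 100.0 * diseased.tracheal_flow / healthy.tracheal_flow


def flow_pressure_curve(
    tree: LungTree,
    pressures: np.ndarray,
    direction: str = "inspiration",
    gas: GasProperties | None = None,
) -> pd.DataFrame:
    """Tracheal flow for a grid of driving pressures (one solve each)."""
    gas = gas or GasProperties()
    rows = []
    for dp in np.asarray(pressures, dtype=float):
        sol = solve_flow(tree, gas, pressure_drop=float(dp), direction=direction)
        rows.append((float(dp), sol.tracheal_flow))
    return pd.DataFrame(rows, columns=["pressure_pa", "flow_m3s"])


def fixture_tree(
    n_generations: int,
    symmetric: bool = True,
    seed: int = 0,
    tracheal_diameter: float = 4e-3,
) -> LungTree:
    """Deterministic miniature tree for oracle tests.

    Builds a complete binary tree of exactly ``n_generations``
    generations (so 2**n - 1 airways); the symmetric variant uses the
    Hess--Murray ratio for both daughters, the asymmetric one adds the
    reference asymmetry and a small seeded dispersion.
    """
    if not 2 <= n_generations <= 8:
        raise ValueError("fixture trees support 2..8 generations")
    r = 2.0 ** (-1.0 / 3.0)
    if symmetric:
        chi_min, chi_maj, sigma = (0.0,), (0.0,), (0.0,)
        d_lim = tracheal_diameter * r ** (n_generations - 0.5)
    else:
        chi_min, chi_maj, sigma = (0.10,), (0.08,), (0.005,)
        h_min, h_maj = 2.0 ** (-1 / 3 - 0.10), 2.0 ** (-1 / 3 + 0.08)
        # just above the minor daughter of the deepest (all-major) path
        d_lim = tracheal_diameter * h_maj ** (n_generations - 1) * h_min * 1.05
    params = GeometryParams(
        tracheal_diameter=tracheal_diameter,
        tracheal_length=3.0 * tracheal_diameter,
        alpha=(3.0,),
        chi_min=chi_min,
        chi_maj=chi_maj,
        sigma=sigma,
        d_lim=d_lim,
        seed=seed,
        max_generations=n_generations + 2,
    )
    tree = generate_tree(params)
    if tree.generation.max() != n_generations:
        raise AssertionError("fixture cutoff did not produce the requested depth")
    return tree
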