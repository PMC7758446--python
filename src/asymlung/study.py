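"""Reference-geometry study: the package's headline quantities.

Runs the standard simulated experiments on freshly generated reference
lungs (one per seed) and aggregates them: terminal-airway counts and
generation mode, terminal Peclet statistics at rest and at moderate
expiration flows, convective delivery metrics under a partial acinar
blockage, the pressure-driven forced-expiration flow, and the
exhaled-NO response of the bundled disease scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .airflow import GasProperties, peclet_numbers, solve_flow
from .exchange import SpeciesParams
from .geometry import (
    GeometryParams,
    apply_acinar_alteration,
    generate_tree,
    select_terminal_extreme,
    terminal_generation_histogram,
)
from .scenarios import canonical_scenarios, delivery_metrics, run_no_scenario
from .transport import solve_feno

__all__ = ["ReferenceStudy", "run_reference_study", "derive_seeds"]

#: scenarios reported by the study, in the order (intra-acinar nearest,
#: pre-acinar liquid, severe perfusion defect)
STUDY_SCENARIOS = ("intra_acinar_near", "preacinar_liquid", "perfusion_severe_far")


def derive_seeds(base_seed: int, n_seeds: int = 5) -> list[int]:
    """Independent 31-bit geometry seeds derived from one base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n_seeds)
    return [int(s % 2**31) for s in state]


@dataclass
class ReferenceStudy:
    """Per-seed quantities plus their across-seed means."""

    seeds: list[int]
    n_term: list[int] = field(default_factory=list)
    modal_generation: list[int] = field(default_factory=list)
    pe_rest_mean: list[float] = field(default_factory=list)      # 50 ml/s
    pe_rest_sd: list[float] = field(default_factory=list)
    pe_exercise_mean: list[float] = field(default_factory=list)  # 250 ml/s
    pe_exercise_sd: list[float] = field(default_factory=list)
    tdel_healthy: list[float] = field(default_factory=list)
    tdel_blocked: list[float] = field(default_factory=list)
    sd_tdel_increase_pct: list[float] = field(default_factory=list)
    sd_omega_increase_pct: list[float] = field(default_factory=list)
    forced_expiratory_flow_lps: list[float] = field(default_factory=list)
    scenario_delta_pct: dict[str, list[float]] = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return float(np.mean(getattr(self, name)))

    def scenario_mean(self, label: str) -> float:
        return float(np.mean(self.scenario_delta_pct[label]))


def run_reference_study(
    seeds: list[int],
    sp: SpeciesParams | None = None,
    gas: GasProperties | None = None,
    *,
    include_scenarios: bool = True,
    feno_flow: float = 50e-6,
    rest_flow: float = 50e-6,
    exercise_flow: float = 250e-6,
    inspiration_time: float = 2.0,
    forcing_pressure: float = 250.0,
) -> ReferenceStudy:
    """Generate one reference lung per seed and measure everything.

    The delivery experiment blocks the 70% of acini farthest from the
    trachea with a linear reduction factor of 0.5 and re-solves the
    inspiratory flow distribution at the same tracheal flow; the NO
    scenarios are run paired against the healthy baseline of the same
    geometry.
    """
    sp = sp or SpeciesParams()
    gas = gas or GasProperties()
    study = ReferenceStudy(seeds=list(seeds))
    study.scenario_delta_pct = {label: [] for label in STUDY_SCENARIOS}
    scen_specs = canonical_scenarios()

    for seed in seeds:
        tree = generate_tree(GeometryParams(seed=seed))
        study.n_term.append(tree.n_term)
        gens, probs = terminal_generation_histogram(tree)
        study.modal_generation.append(int(gens[np.argmax(probs)]))

        flow_rest = solve_flow(tree, gas, tracheal_flow=rest_flow,
                               direction="expiration")
        pe = peclet_numbers(tree, flow_rest, gas.diffusivity)[tree.terminal]
        study.pe_rest_mean.append(float(pe.mean()))
        study.pe_rest_sd.append(float(pe.std()))

        flow_ex = solve_flow(tree, gas, tracheal_flow=exercise_flow,
                             direction="inspiration")
        pe = peclet_numbers(tree, flow_ex, gas.diffusivity)[tree.terminal]
        study.pe_exercise_mean.append(float(pe.mean()))
        study.pe_exercise_sd.append(float(pe.std()))

        met0 = delivery_metrics(tree, flow_ex, t_ins=inspiration_time)
        blocked = select_terminal_extreme(tree, 0.7, "farthest")
        tree_b = apply_acinar_alteration(tree, blocked, phi=0.5)
        flow_b = solve_flow(tree_b, gas, tracheal_flow=exercise_flow,
                            direction="inspiration")
        met1 = delivery_metrics(tree_b, flow_b, t_ins=inspiration_time)
        study.tdel_healthy.append(float(met0.delivery_time.mean()))
        study.tdel_blocked.append(float(met1.delivery_time.mean()))
        study.sd_tdel_increase_pct.append(
            100.0 * (met1.delivery_time.std() - met0.delivery_time.std())
            / met0.delivery_time.std()
        )
        study.sd_omega_increase_pct.append(
            100.0 * (met1.supply_ratio.std() - met0.supply_ratio.std())
            / met0.supply_ratio.std()
        )

        forced = solve_flow(tree, gas, pressure_drop=forcing_pressure,
                            direction="expiration")
        study.forced_expiratory_flow_lps.append(1e3 * forced.tracheal_flow)

        if include_scenarios:
            if feno_flow == rest_flow:
                flow_feno = flow_rest
            else:
                flow_feno = solve_flow(tree, gas, tracheal_flow=feno_flow,
                                       direction="expiration")
            baseline = solve_feno(tree, flow_feno, sp, gas)
            for label in STUDY_SCENARIOS:
                res = run_no_scenario(tree, scen_specs[label], sp, gas,
                                      baseline=baseline)
                study.scenario_delta_pct[label].append(res["delta_feno_pct"])
    return study
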