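"""Steady and unsteady lumen transport solvers."""

import numpy as np
import pytest

from asymlung import (
    GasProperties,
    SpeciesParams,
    apply_acinar_alteration,
    solve_feno,
    solve_flow,
    solve_steady,
    solve_unsteady,
    steady_airway_solution,
)
from asymlung.acinus import build_linkings
from asymlung.exchange import ppb_to_molar, wall_flux_density
from asymlung.geometry import GeometryParams, LungTree
from asymlung.scenarios import fixture_tree
from asymlung.transport import (
    assemble_steady_system,
    global_balance_residual,
)


class TestSteadyAirwaySolution:
    @pytest.mark.parametrize(
        "v,length,source,direction",
        [
            (0.05, 5e-3, 1e-6, "expiration"),
            (0.05, 5e-3, 1e-6, "inspiration"),
            (2.0, 1e-2, 3e-7, "expiration"),
            (0.0, 5e-3, 1e-6, "expiration"),
        ],
    )
    def test_residual_of_the_ode_vanishes(self, gas, v, length, source, direction):
        """Plug the closed-form solution and its analytic derivatives back
        into the convection--diffusion balance on 100 points."""
        sol = steady_airway_solution(v, length, gas.diffusivity, source, direction)
        a, b = 2e-7, 5e-8
        z = np.linspace(0.0, length, 100)
        c1 = sol.gradient(z, a, b)
        c2 = b * sol.lam**2 * sol.basis(z)
        if sol.degenerate:
            c2 = c2 - source / gas.diffusivity
        d = 1.0 if direction == "inspiration" else -1.0
        residual = gas.diffusivity * c2 - d * v * c1 + source
        scale = max(source, gas.diffusivity * np.max(np.abs(c2)), 1e-12)
        assert np.max(np.abs(residual)) < 1e-10 * scale

    def test_pure_diffusion_profile_is_linear(self, gas):
        sol = steady_airway_solution(0.0, 1e-2, gas.diffusivity, 0.0, "expiration")
        z = np.linspace(0, 1e-2, 5)
        c = sol.concentration(z, 1.0, 0.5)
        assert np.allclose(np.diff(c, 2), 0.0, atol=1e-12)

    def test_zero_exponential_weight_gives_constant(self, gas):
        sol = steady_airway_solution(0.1, 1e-2, gas.diffusivity, 0.0, "expiration")
        z = np.linspace(0, 1e-2, 5)
        assert np.allclose(sol.concentration(z, 2.0, 0.0), 2.0)


def _single_airway_tree(geom: GeometryParams) -> LungTree:
    """A one-airway 'tree' (the trachea is itself terminal)."""
    n = 1
    return LungTree(
        generation=np.array([1]),
        index=np.array([1]),
        parent=np.array([-1]),
        child_minor=np.array([-1]),
        child_major=np.array([-1]),
        diameter=np.array([1e-3]),
        length=np.array([5e-3]),
        delta_mu=np.full(n, geom.delta_mu),
        delta_e=np.full(n, geom.delta_e),
        delta_m=np.full(n, geom.delta_m),
        phi=np.ones(n),
        gamma=np.ones(n),
        params=geom,
        seed=0,
    )


class TestAssembly:
    def test_system_size_is_twice_the_airway_count(self, asymmetric_tree, sp, gas):
        flow = solve_flow(asymmetric_tree, gas, tracheal_flow=1e-5,
                         direction="expiration")
        term = asymmetric_tree.terminal_ids
        a, b = build_linkings(
            asymmetric_tree.gamma[term], flow.flow[term] / 2.0,
            asymmetric_tree.params, sp, gas, "expiration",
        )
        j = wall_flux_density(
            sp=sp, delta_mu=asymmetric_tree.delta_mu,
            delta_e=asymmetric_tree.delta_e, delta_m=asymmetric_tree.delta_m,
        )
        mat, rhs, _ = assemble_steady_system(
            asymmetric_tree, flow, 4 * j / asymmetric_tree.diameter, a, b,
            "expiration", 0.0, gas.diffusivity,
        )
        assert mat.shape == (2 * asymmetric_tree.n_airw, 2 * asymmetric_tree.n_airw)
        assert rhs.size == 2 * asymmetric_tree.n_airw

    def test_single_airway_solve_matches_hand_algebra(self, geom, sp, gas):
        """2x2 system: mouth no-diffusion row plus the acinar linking row,
        solved by direct substitution."""
        tree = _single_airway_tree(geom)
        flow = solve_flow(tree, gas, tracheal_flow=1e-7, direction="expiration")
        field = solve_steady(tree, flow, sp, gas, "expiration")

        v = flow.velocity[0]
        dg = gas.diffusivity
        lam = -v / dg
        length = tree.length[0]
        j = wall_flux_density(sp=sp, delta_mu=tree.delta_mu[0],
                              delta_e=tree.delta_e[0], delta_m=tree.delta_m[0])
        s = 4 * j / tree.diameter[0]
        slope_g = s / (-v)
        a_l, b_l = build_linkings(
            np.array([1.0]), np.array([flow.flow[0] / 2.0]), geom, sp, gas,
            "expiration",
        )
        # mouth row: B*lam + slope_g = 0
        b_coef = -slope_g / lam
        # terminal row: D^2 (B lam e^{lam L} + slope_g)
        #             = 2 (phi Da)^2 (a (A + B e^{lam L} + slope_g L) + b)
        d2 = tree.diameter[0] ** 2
        kk = 2.0 * (geom.acinar_diameter) ** 2
        el = np.exp(lam * length)
        a_coef = (
            d2 * (b_coef * lam * el + slope_g) / (kk * a_l[0])
            - b_l[0] / a_l[0] - b_coef * el - slope_g * length
        )
        assert field.coeff_b[0] == pytest.approx(b_coef, rel=1e-10)
        assert field.coeff_a[0] == pytest.approx(a_coef, rel=1e-10)

    def test_flux_row_annihilates_constant_fields(self, symmetric_tree, sp, gas):
        # a uniform concentration has zero gradients everywhere, so every
        # bifurcation flux row must evaluate to zero on it
        flow = solve_flow(symmetric_tree, gas, tracheal_flow=1e-5,
                         direction="expiration")
        term = symmetric_tree.terminal_ids
        a, b = build_linkings(
            symmetric_tree.gamma[term], flow.flow[term] / 2.0,
            symmetric_tree.params, sp, gas, "expiration",
        )
        n = symmetric_tree.n_airw
        mat, _, basis = assemble_steady_system(
            symmetric_tree, flow, np.zeros(n), a, b, "expiration", 0.0,
            gas.diffusivity,
        )
        const = np.zeros(2 * n)
        const[0::2] = 1.0  # A_k = 1, B_k = 0 encodes C == 1
        resid = mat @ const
        inner = np.flatnonzero(~symmetric_tree.terminal)
        flux_rows = 1 + 3 * np.arange(inner.size) + 2
        assert np.max(np.abs(resid[flux_rows])) < 1e-12


class TestSolveFeno:
    def test_sourceless_lungs_exhale_nothing(self, symmetric_tree, gas):
        sp0 = SpeciesParams(production_rate=0.0, c_eq_ppb=0.0, c_in_ppb=0.0)
        flow = solve_flow(symmetric_tree, gas, tracheal_flow=1e-5,
                         direction="expiration")
        field = solve_feno(symmetric_tree, flow, sp0, gas)
        assert field.feno_ppb == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(field.distal_concentrations(), 0.0, atol=1e-18)

    def test_concentrations_are_positive(self, asymmetric_tree, sp, gas):
        flow = solve_flow(asymmetric_tree, gas, tracheal_flow=1e-5,
                         direction="expiration")
        field = solve_feno(asymmetric_tree, flow, sp, gas)
        assert field.feno_ppb > 0
        assert np.all(field.distal_concentrations() > 0)
        assert np.all(field.proximal_concentrations() > 0)

    def test_global_balance_closes(self, asymmetric_tree, sp, gas):
        flow = solve_flow(asymmetric_tree, gas, tracheal_flow=1e-5,
                         direction="expiration")
        field = solve_feno(asymmetric_tree, flow, sp, gas)
        assert global_balance_residual(field, asymmetric_tree, flow, sp) < 1e-6

    def test_back_diffusion_signature(self, reference_tree, sp, gas):
        """Exhaled fraction falls with flow while total output rises."""
        fenos, outputs = [], []
        for q in (25e-6, 50e-6, 100e-6):
            flow = solve_flow(reference_tree, gas, tracheal_flow=q,
                             direction="expiration")
            f = solve_feno(reference_tree, flow, sp, gas).feno_ppb
            fenos.append(f)
            outputs.append(f * q)
        assert np.all(np.diff(fenos) < 0)
        assert np.all(np.diff(outputs) > 0)

    def test_feno_versus_inverse_flow_is_concave(self, reference_tree, sp, gas):
        flows = np.array([25e-6, 50e-6, 100e-6])
        inv_q = 1.0 / flows[::-1]
        fenos = []
        for q in flows[::-1]:
            flow = solve_flow(reference_tree, gas, tracheal_flow=q,
                             direction="expiration")
            fenos.append(solve_feno(reference_tree, flow, sp, gas).feno_ppb)
        slopes = np.diff(fenos) / np.diff(inv_q)
        assert slopes[1] < slopes[0]

    def test_generation_profile_has_three_segments(
        self, reference_tree, reference_expiration_flow, sp, gas
    ):
        """Distal plateau, mid-tree rise, proximal plateau."""
        field = solve_feno(reference_tree, reference_expiration_flow, sp, gas)
        prof = field.generation_profile().set_index("generation_index")["mean_ppb"]
        distal = prof.loc[16:].to_numpy()
        rise = prof.loc[5:14].to_numpy()
        proximal = prof.loc[0:4].to_numpy()
        total = prof.loc[0] - prof.loc[prof.index.max()]
        assert abs(distal[0] - distal[-1]) < 0.25 * total
        assert abs(proximal[0] - proximal[-1]) < 0.15 * total
        assert (rise[0] - rise[-1]) > 0.5 * total


class TestUnsteady:
    def test_long_time_limit_recovers_the_steady_field(self, symmetric_tree, sp, gas):
        """Refining the grid shrinks the steady-state mismatch at first
        order; on the finest grid the whole field agrees within 0.5%."""
        flow = solve_flow(symmetric_tree, gas, tracheal_flow=1e-6,
                         direction="expiration")
        steady = solve_feno(symmetric_tree, flow, sp, gas)
        errors = []
        for n_cells in (24, 48, 96):
            cells = np.full(symmetric_tree.n_airw, n_cells)
            res = solve_unsteady(
                symmetric_tree, flow, sp, gas, direction="expiration",
                t_end=80.0, dt=0.02, cells_per_airway=cells,
            )
            worst = 0.0
            for k in range(symmetric_tree.n_airw):
                z = res.cell_centres(k)
                exact = steady.concentration(k, z)
                got = res.airway_cells(k)
                worst = max(worst, np.max(np.abs(got - exact) / np.abs(exact)))
            errors.append(worst)
        assert errors[0] > errors[1] > errors[2]
        assert 1.4 < errors[0] / errors[1] < 3.0  # first order in the cell size
        assert errors[2] < 0.005
        assert res.mouth_ppb[-1] == pytest.approx(steady.feno_ppb, rel=0.005)

    def test_equilibrium_is_preserved_without_sources(self, symmetric_tree, gas):
        sp0 = SpeciesParams(production_rate=0.0, c_eq_ppb=5.0, c_in_ppb=5.0)
        flow = solve_flow(symmetric_tree, gas, tracheal_flow=1e-6,
                         direction="expiration")
        c0 = ppb_to_molar(5.0)
        res = solve_unsteady(
            symmetric_tree, flow, sp0, gas, direction="expiration",
            t_end=2.0, dt=0.05, initial=c0,
        )
        assert np.allclose(res.concentrations, c0, rtol=1e-10)

    def test_positivity_with_nonnegative_sources(self, asymmetric_tree, sp, gas):
        flow = solve_flow(asymmetric_tree, gas, tracheal_flow=1e-5,
                         direction="expiration")
        res = solve_unsteady(
            asymmetric_tree, flow, sp, gas, direction="expiration",
            t_end=5.0, dt=0.05, initial=0.0,
        )
        assert np.all(res.concentrations >= 0.0)
        assert np.all(res.mouth_ppb >= 0.0)

    def test_mouth_concentration_rises_then_plateaus(self, asymmetric_tree, sp, gas):
        flow = solve_flow(asymmetric_tree, gas, tracheal_flow=1e-5,
                         direction="expiration")
        res = solve_unsteady(
            asymmetric_tree, flow, sp, gas, direction="expiration",
            t_end=20.0, dt=0.02, initial=0.0,
        )
        t = res.times
        early = res.mouth_ppb[t <= 2.0]
        late = res.mouth_ppb[t >= 15.0]
        assert early[-1] > early[0]
        assert np.ptp(late) < 0.02 * late.mean()
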