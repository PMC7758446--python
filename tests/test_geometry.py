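"""Tree generation, airway selection and structural alterations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asymlung import (
    GeometryParams,
    apply_acinar_alteration,
    apply_lumen_alteration,
    base_ratios,
    daughter_ratios,
    generate_tree,
    select_airways,
    terminal_generation_histogram,
)
from asymlung.geometry import (
    ancestors_of,
    select_by_diameter,
    select_terminal_extreme,
)
from asymlung.scenarios import fixture_tree

CBRT_HALF = 2.0 ** (-1.0 / 3.0)


class TestBaseRatios:
    def test_symmetric_case_recovers_hess_murray(self):
        h_min, h_maj = base_ratios(0.0, 0.0)
        assert h_min == pytest.approx(CBRT_HALF, abs=1e-15)
        assert h_maj == pytest.approx(CBRT_HALF, abs=1e-15)

    def test_reference_asymmetry_values(self):
        h_min, h_maj = base_ratios(0.10, 0.08)
        assert h_min == pytest.approx(2.0 ** (-1 / 3 - 0.10), rel=1e-14)
        assert h_maj == pytest.approx(2.0 ** (-1 / 3 + 0.08), rel=1e-14)
        assert h_min == pytest.approx(0.7406, abs=5e-4)
        assert h_maj == pytest.approx(0.8390, abs=5e-4)

    def test_major_ratio_reaching_unity_is_rejected(self):
        with pytest.raises(ValueError):
            base_ratios(0.0, 1.0 / 3.0)


class TestDaughterRatios:
    def test_zero_dispersion_is_identity(self):
        assert daughter_ratios(0.74, 0.84, 0.0, 2.3) == (0.74, 0.84)

    def test_shifted_minor_and_volume_conserving_major(self):
        h_min, h_maj = daughter_ratios(0.74, 0.84, 0.05, 1.0)
        assert h_min == pytest.approx(0.79)
        assert h_maj == pytest.approx((0.84**3 + 0.74**3 - 0.79**3) ** (1 / 3))

    @given(
        chi_min=st.floats(0.0, 0.2),
        chi_maj=st.floats(0.0, 0.2),
        sigma=st.floats(0.0, 0.1),
        x=st.floats(-3.0, 3.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_cubed_sum_invariant(self, chi_min, chi_maj, sigma, x):
        """Daughter-volume conservation holds for every accepted draw."""
        h0_min, h0_maj = base_ratios(chi_min, chi_maj)
        try:
            h_min, h_maj = daughter_ratios(h0_min, h0_maj, sigma, x)
        except ValueError:
            return  # rejected draw; the generator would redraw
        assert h_min**3 + h_maj**3 == pytest.approx(
            h0_min**3 + h0_maj**3, rel=1e-14
        )


class TestGenerateTree:
    def test_binary_tree_identity_and_root_dimensions(self, reference_tree, geom):
        assert reference_tree.n_airw == 2 * reference_tree.n_term - 1
        assert reference_tree.diameter[0] == geom.tracheal_diameter
        assert reference_tree.length[0] == geom.tracheal_length

    def test_lengths_follow_aspect_ratio(self, reference_tree, geom):
        k = np.flatnonzero(reference_tree.generation == 3)
        assert np.allclose(
            reference_tree.length[k], 1.75 * reference_tree.diameter[k]
        )

    def test_diameters_strictly_decrease_toward_the_periphery(self, reference_tree):
        t = reference_tree
        inner = ~t.terminal
        assert np.all(t.diameter[t.child_minor[inner]] < t.diameter[inner])
        assert np.all(t.diameter[t.child_major[inner]] < t.diameter[inner])

    def test_fixed_seed_is_bit_reproducible(self):
        p = GeometryParams(seed=42)
        a, b = generate_tree(p), generate_tree(p)
        assert np.array_equal(a.diameter, b.diameter)
        assert np.array_equal(a.length, b.length)
        assert np.array_equal(a.parent, b.parent)

    def test_terminal_daughters_would_fall_below_cutoff(self, reference_tree, geom):
        # every terminal's minor daughter (noise-free estimate) is near or
        # below the cutoff; every parent of two airways is above it
        t = reference_tree
        assert t.diameter[t.terminal].min() > geom.cutoff_diameter
        assert t.diameter[~t.terminal].min() > geom.cutoff_diameter

    def test_runaway_parameters_hit_generation_guard(self):
        p = GeometryParams(d_lim=1e-9, max_generations=12)
        with pytest.raises(RuntimeError):
            generate_tree(p)

    def test_phi_gamma_default_to_one_on_terminals(self, reference_tree):
        assert np.all(reference_tree.phi == 1.0)
        assert np.all(reference_tree.gamma == 1.0)


class TestTerminalHistogram:
    def test_probabilities_sum_to_one(self, reference_tree):
        gens, probs = terminal_generation_histogram(reference_tree)
        assert probs.sum() == pytest.approx(1.0)
        assert gens.min() >= 1

    def test_dispersion_broadens_the_distribution(self):
        sharp = generate_tree(GeometryParams(sigma=(0, 0, 0, 0, 0, 0), seed=0))
        broad = generate_tree(GeometryParams(seed=0))
        g_s, p_s = terminal_generation_histogram(sharp)
        g_b, p_b = terminal_generation_histogram(broad)
        assert g_b.max() > g_s.max() or p_b.max() < p_s.max()

    def test_single_airway_tree_is_a_point_mass(self):
        p = GeometryParams(d_lim=1.4e-2)  # daughters of the trachea are cut
        t = generate_tree(p)
        assert t.n_airw == 1 and t.n_term == 1
        gens, probs = terminal_generation_histogram(t)
        assert list(gens) == [1] and probs[0] == 1.0


class TestSelection:
    def test_full_random_fraction_returns_all_terminals(self, symmetric_tree):
        ids = select_airways(
            symmetric_tree, {"kind": "random_fraction", "fraction": 1.0, "seed": 0}
        )
        assert np.array_equal(ids, symmetric_tree.terminal_ids)

    def test_farthest_half_is_an_order_statistic_on_generations(self):
        tree = fixture_tree(4, symmetric=False, seed=5)
        term = tree.terminal_ids
        chosen = select_terminal_extreme(tree, 0.5, "farthest")
        left_out = np.setdiff1d(term, chosen)
        assert tree.generation[chosen].min() >= tree.generation[left_out].max() - 1
        assert chosen.size == round(0.5 * term.size)

    def test_small_airways_exclude_the_trachea(self, reference_tree):
        ids = select_by_diameter(reference_tree, 2e-3)
        assert 0 not in ids
        assert np.all(reference_tree.diameter[ids] < 2e-3)

    def test_ancestor_closure_is_deduplicated(self, symmetric_tree):
        term = symmetric_tree.terminal_ids
        anc = ancestors_of(symmetric_tree, term, 10)
        assert np.array_equal(
            np.sort(np.concatenate([anc, term])), np.arange(symmetric_tree.n_airw)
        )

    def test_unknown_criterion_raises(self, symmetric_tree):
        with pytest.raises(ValueError):
            select_airways(symmetric_tree, {"kind": "by_vibes"})


class TestLumenAlteration:
    def test_zero_beta_is_identity(self, symmetric_tree):
        out = apply_lumen_alteration(
            symmetric_tree, symmetric_tree.terminal_ids, 0.0, "liquid"
        )
        assert np.array_equal(out.diameter, symmetric_tree.diameter)
        assert np.array_equal(out.delta_mu, symmetric_tree.delta_mu)

    def test_half_area_reduction_shrinks_diameter_by_sqrt2(self, symmetric_tree):
        out = apply_lumen_alteration(symmetric_tree, [0], 0.5, "muscle")
        assert out.diameter[0] == pytest.approx(
            symmetric_tree.diameter[0] / np.sqrt(2.0), rel=1e-14
        )

    @pytest.mark.parametrize("beta", [0.3, 0.5, 0.8775])
    def test_muscle_mode_conserves_each_annulus_area(self, beta):
        tree = fixture_tree(2, symmetric=True, tracheal_diameter=600e-6)
        out = apply_lumen_alteration(tree, [0], beta, "muscle")
        for before, after in [(tree, out)]:
            r_old = [before.diameter[0] / 2]
            r_new = [after.diameter[0] / 2]
            for layer in ("delta_mu", "delta_e", "delta_m"):
                r_old.append(r_old[-1] + getattr(before, layer)[0])
                r_new.append(r_new[-1] + getattr(after, layer)[0])
        for k in range(3):
            area_old = r_old[k + 1] ** 2 - r_old[k] ** 2
            area_new = r_new[k + 1] ** 2 - r_new[k] ** 2
            assert area_new == pytest.approx(area_old, rel=1e-12)

    def test_liquid_mode_only_thickens_the_liquid_layer(self, symmetric_tree):
        out = apply_lumen_alteration(symmetric_tree, [0], 0.5, "liquid")
        d_loss = (symmetric_tree.diameter[0] - out.diameter[0]) / 2
        assert out.delta_mu[0] == pytest.approx(
            symmetric_tree.delta_mu[0] + d_loss, rel=1e-14
        )
        assert out.delta_e[0] == symmetric_tree.delta_e[0]
        assert out.delta_m[0] == symmetric_tree.delta_m[0]

    def test_alterations_compose_and_validate(self, symmetric_tree):
        once = apply_lumen_alteration(symmetric_tree, [0], 0.5, "liquid")
        twice = apply_lumen_alteration(once, [0], 0.5, "liquid")
        assert twice.diameter[0] == pytest.approx(symmetric_tree.diameter[0] / 2)
        with pytest.raises(ValueError):
            apply_lumen_alteration(symmetric_tree, [0], 1.0, "liquid")
        with pytest.raises(ValueError):
            apply_lumen_alteration(symmetric_tree, [0], 0.5, "osmosis")


class TestAcinarAlteration:
    def test_identity_values(self, symmetric_tree):
        out = apply_acinar_alteration(
            symmetric_tree, symmetric_tree.terminal_ids, phi=1.0, gamma=1.0
        )
        assert np.array_equal(out.phi, symmetric_tree.phi)
        assert np.array_equal(out.gamma, symmetric_tree.gamma)

    def test_sets_only_selected_terminals(self, symmetric_tree):
        ids = symmetric_tree.terminal_ids[:2]
        out = apply_acinar_alteration(symmetric_tree, ids, phi=0.5, gamma=0.7)
        assert np.all(out.phi[ids] == 0.5) and np.all(out.gamma[ids] == 0.7)
        rest = np.setdiff1d(symmetric_tree.terminal_ids, ids)
        assert np.all(out.phi[rest] == 1.0) and np.all(out.gamma[rest] == 1.0)

    def test_rejects_non_terminals_and_zero_phi(self, symmetric_tree):
        with pytest.raises(ValueError):
            apply_acinar_alteration(symmetric_tree, [0], phi=0.5)
        with pytest.raises(ValueError):
            apply_acinar_alteration(
                symmetric_tree, symmetric_tree.terminal_ids[:1], phi=0.0
            )
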