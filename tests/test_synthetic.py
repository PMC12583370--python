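"""Ground-truth generator: exact topology, determinism, rendering truth."""

import dataclasses

import numpy as np
import pytest
from skimage.morphology import skeletonize as sk_skeletonize

from mitomorph import morphometry as morph
from mitomorph import synthetic as syn


def _counts(net):
    g = morph.build_graph(net.skeleton)
    return g.branch_count, g.junction_count, g.rod_count


class TestGenerateNetwork:
    def test_rods_only(self):
        net = syn.generate_network(5, 0, 5, image_shape=(256, 256), seed=1)
        assert (net.true_branch_count, net.true_junction_count, net.true_rod_count) == (5, 0, 5)
        assert _counts(net) == (5, 0, 5)

    def test_minimal_y_component(self):
        net = syn.generate_network(3, 1, 0, seed=2)
        g = morph.build_graph(net.skeleton)
        assert (g.branch_count, g.junction_count, g.rod_count) == (3, 1, 0)
        assert g.endpoint_count == 3
        assert g.component_count == 1

    def test_mixed_network_round_trip(self, small_network):
        assert _counts(small_network) == (12, 4, 3)

    @pytest.mark.parametrize("seed", range(0, 120, 7))
    def test_round_trip_exact_random_topologies(self, seed):
        rng = np.random.default_rng(seed)
        b = int(rng.integers(3, 31))
        j = int(rng.integers(0, 11))
        if j == 0:
            r = b
        else:
            lo, hi = max(0, b - 4 * j), b - (2 * j + 1)
            if hi < lo:
                j, r = 0, b
            else:
                r = int(rng.integers(lo, hi + 1))
        net = syn.generate_network(b, j, r, seed=seed)
        assert _counts(net) == (b, j, r)

    def test_branch_lengths_match_graph_builder(self, small_network):
        g = morph.build_graph(small_network.skeleton)
        assert sorted(g.branch_pixel_counts) == sorted(small_network.true_branch_lengths)

    def test_skeleton_is_thinning_fixed_point(self, small_network):
        assert np.array_equal(
            sk_skeletonize(small_network.skeleton), small_network.skeleton
        )

    def test_determinism(self):
        a = syn.generate_network(10, 3, 2, seed=5)
        b = syn.generate_network(10, 3, 2, seed=5)
        assert np.array_equal(a.skeleton, b.skeleton)
        assert a.true_branch_lengths == b.true_branch_lengths

    def test_rods_are_junction_free_components(self):
        net = syn.generate_network(8, 0, 8, seed=3)
        g = morph.build_graph(net.skeleton)
        assert g.junction_count == 0
        assert g.component_count == 8

    def test_infeasible_counts_rejected(self):
        with pytest.raises(syn.InfeasiblePackingError):
            syn.generate_network(5, 0, 2, seed=0)  # tree branches need junctions
        with pytest.raises(syn.InfeasiblePackingError):
            syn.generate_network(4, 3, 3, seed=0)  # 1 tree branch, needs >= 3
        with pytest.raises(syn.InfeasiblePackingError):
            syn.generate_network(3, 1, 4, seed=0)  # rods > branches

    def test_image_too_small_raises(self):
        with pytest.raises(syn.InfeasiblePackingError):
            syn.generate_network(
                20, 6, 2, image_shape=(32, 32), length_range=(12, 16), seed=0
            )


class TestRenderField:
    def test_noiseless_calcium_compartment_means_exact(self, noiseless_field):
        t = noiseless_field.truth
        ca = noiseless_field.calcium_channel
        levels = t["calcium_levels"]
        assert ca[t["mito_mask"]].mean() == pytest.approx(levels["mito"], abs=1e-9)
        assert ca[t["er_mask"]].mean() == pytest.approx(levels["er"], abs=1e-9)
        assert ca[t["cell_mask"]].mean() == pytest.approx(levels["whole_cell"], abs=1e-9)

    def test_determinism_bit_identical(self, small_network):
        spec = syn.RenderSpec(seed=9)
        a = syn.render_field(small_network, render_spec=spec)
        b = syn.render_field(small_network, render_spec=spec)
        for ch in ("calcium_channel", "mito_channel", "er_channel"):
            assert np.array_equal(getattr(a, ch), getattr(b, ch))
        assert np.array_equal(a.controls["mito"], b.controls["mito"])

    def test_noisy_corrected_mito_mean_within_clt_bound(self):
        """Mean recovery over many fields stays within 3 sigma / sqrt(n_px)."""
        n_ok, n = 0, 50
        rng = np.random.default_rng(0)
        for _ in range(n):
            net = syn.generate_network(
                16, 4, 4, image_shape=(192, 192), seed=int(rng.integers(2**31 - 1))
            )
            spec = syn.RenderSpec(noise_sd=5.0, background_level=10.0,
                                  seed=int(rng.integers(2**31 - 1)))
            fld = syn.render_field(net, render_spec=spec)
            mask = fld.truth["mito_mask"]
            got = fld.calcium_channel[mask].mean()
            bound = 3 * spec.noise_sd / np.sqrt(mask.sum())
            n_ok += abs(got - fld.truth["calcium_levels"]["mito"]) <= bound
        assert n_ok >= int(0.95 * n)

    def test_er_mask_disjoint_from_mito_by_default(self, noiseless_field):
        t = noiseless_field.truth
        assert not (t["er_mask"] & t["mito_mask"]).any()

    def test_calcium_level_below_background_rejected(self, small_network):
        with pytest.raises(ValueError, match="below background"):
            syn.render_field(
                small_network,
                calcium_levels=syn.CalciumLevels(whole_cell=5.0),
                render_spec=syn.RenderSpec(background_level=10.0),
            )

    def test_render_spec_validation(self):
        with pytest.raises(ValueError):
            syn.RenderSpec(psf_sigma=0.0)
        with pytest.raises(ValueError):
            syn.RenderSpec(tube_radius=0)
        with pytest.raises(ValueError):
            syn.RenderSpec(noise_sd=-1.0)


class TestGenerateExperiment:
    def test_minimal_design_valid(self):
        spec = syn.EffectSpec(n_replicates=2, fields_per_replicate=1, seed=0)
        exp = syn.generate_experiment(spec)
        assert len(exp.field_table) == 3 * 2 * 2 * 1
        # every cell of the factorial design is present and balanced
        sizes = exp.field_table.groupby(["katp_level", "rotenone"]).size()
        assert sizes.nunique() == 1

    def test_design_validation(self):
        with pytest.raises(ValueError):
            syn.EffectSpec(n_replicates=1)
        with pytest.raises(ValueError):
            syn.EffectSpec(fields_per_replicate=0)
        with pytest.raises(ValueError):
            syn.EffectSpec(within_sd={**syn._DEFAULT_WITHIN_SD, "ca_mito": -1.0})

    def test_tabular_determinism(self):
        a = syn.generate_experiment(syn.EffectSpec(seed=4, n_replicates=2))
        b = syn.generate_experiment(syn.EffectSpec(seed=4, n_replicates=2))
        assert a.field_table.equals(b.field_table)
        assert a.mtt_wells.equals(b.mtt_wells)

    def test_null_spec_has_equal_condition_means(self):
        spec = syn.EffectSpec.null(seed=0)
        means = {
            (a, b): spec.condition_mean("fragmentation", a, b)
            for a in spec.factor_a_levels
            for b in spec.factor_b_levels
        }
        assert len(set(means.values())) == 1

    def test_default_effect_directions(self):
        spec = syn.EffectSpec()
        base = spec.baselines
        assert spec.condition_mean("fragmentation", "ctrl", "rot") > base["fragmentation"]
        assert spec.condition_mean("branching", "ctrl", "rot") < base["branching"]
        for v in ("ca_whole_cell", "ca_mito", "ca_er"):
            assert spec.condition_mean(v, "ctrl", "rot") < base[v]
        for lv in ("agonist", "antagonist"):
            assert (
                spec.condition_mean("mean_branch_length_um", lv, "veh")
                > base["mean_branch_length_um"]
            )

    def test_rendered_fields_carry_condition_labels(self):
        spec = syn.EffectSpec(n_replicates=2, fields_per_replicate=1, seed=1)
        exp = syn.generate_experiment(spec, render=True)
        assert len(exp.fields) == len(exp.field_table)
        got = {(f.katp_level, f.rotenone) for f in exp.fields}
        assert got == {(a, b) for a in spec.factor_a_levels for b in spec.factor_b_levels}


def test_topology_for_targets_feasible_over_grid():
    """The target->integer-topology map always yields generatable counts."""
    for frag in np.linspace(0, 1, 11):
        for br in np.linspace(0, 0.5, 6):
            b, j, r = syn._topology_for_targets(frag, br, 16)
            net = syn.generate_network(b, j, r, seed=0)
            assert (net.true_branch_count, net.true_junction_count, net.true_rod_count) == (b, j, r)
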