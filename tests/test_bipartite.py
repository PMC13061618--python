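"""Variable-mask series, texture models, harmonic selection, BII, subfield
manipulations, controls, and radial-frequency analysis."""

import numpy as np
import pytest

from veiscope import (
    SynthesisConfig,
    bipartite_analysis,
    bipartite_invariance_index,
    gabor_image,
    harmonic_selection,
    median_radial_frequency,
    no_spatial_division_veis,
    optimize_texture,
    render_texture_veis,
    subfield_manipulation,
    subfield_median_frequency,
    two_variable_veis,
    variable_mask_series,
)
from veiscope.bipartite import SubfieldMasks
from veiscope.models import GaborParams
from veiscope.synthesis import VEISet
from veiscope.synthetic import naturalistic_images
from tests.conftest import FAST_CONFIG

SCALED = dict(n_steps=150, n_crops=8, n_refine_iters=100)


def _veiset(images, mask):
    from veiscope.images import pairwise_masked_distances

    d = pairwise_masked_distances(images, mask)
    return VEISet(images=images, activations=np.ones(len(images)),
                  lambda_used=0.0, min_pairwise_distance=float(d.min()),
                  mean_pairwise_distance=float(d.mean()))


class TestVariableMaskSeries:
    @pytest.fixture(scope="class")
    def left_heavy(self):
        rng = np.random.default_rng(0)
        m_mei = np.zeros((20, 40))
        m_mei[4:16, 4:36] = 1.0
        imgs = []
        for _ in range(10):
            im = 0.02 * rng.standard_normal((20, 40))
            im[:, :20] += rng.standard_normal((20, 20))   # variance on the left
            imgs.append(im)
        return _veiset(imgs, m_mei), m_mei

    def test_high_variance_half_captured(self, left_heavy):
        veis, m_mei = left_heavy
        series = variable_mask_series(veis, m_mei, fractions=(0.5,))
        m_v = series[0].m_v
        assert m_v[:, 20:].sum() == 0
        assert m_v[:, :20].sum() > 0

    def test_fractions_achieved_against_cumsum_oracle(self, left_heavy):
        veis, m_mei = left_heavy
        var_map = np.stack(veis.images).var(axis=0) * (m_mei > 0)
        total = var_map.sum()
        for masks in variable_mask_series(veis, m_mei,
                                          fractions=(0.2, 0.4, 0.6)):
            captured = var_map[masks.m_v > 0].sum() / total
            largest_px = var_map.max() / total
            target = masks.variance_fraction
            assert captured == pytest.approx(target, abs=1e-12)
            # achieved within one pixel's variance of the requested fraction
            assert captured >= 0.2 - 1e-12
            assert any(abs(captured - f) <= largest_px
                       for f in (0.2, 0.4, 0.6))

    def test_masks_partition_the_mei_mask(self, left_heavy):
        veis, m_mei = left_heavy
        for masks in variable_mask_series(veis, m_mei, fractions=(0.3,)):
            np.testing.assert_allclose(masks.m_v + masks.m_f, m_mei)

    def test_full_fraction_covers_support(self, left_heavy):
        veis, m_mei = left_heavy
        masks = variable_mask_series(veis, m_mei, fractions=(1.0,))[0]
        np.testing.assert_allclose(masks.m_v > 0, m_mei > 0)

    def test_uniform_variance_flagged(self):
        m_mei = np.ones((8, 8))
        imgs = [np.zeros((8, 8)), np.ones((8, 8))]   # identical variance everywhere
        with pytest.raises(ValueError, match="uniform"):
            variable_mask_series(_veiset(imgs, m_mei), m_mei)


class TestTextureModel:
    def test_complex_cell_full_texture_crops_keep_activation(self, complex_cell,
                                                             complex_mei):
        cfg = SynthesisConfig(seed=0, **FAST_CONFIG)
        full = SubfieldMasks(m_mei=complex_mei.mask, m_v=complex_mei.mask,
                             m_f=np.zeros_like(complex_mei.mask),
                             variance_fraction=1.0)
        canvas = optimize_texture(complex_cell, full, None, cfg, n_steps=300,
                                  n_crops=8, seed=1)
        rendered = render_texture_veis(canvas, full, None, n=20, seed=2,
                                       config=cfg, model=complex_cell)
        assert rendered.activations.mean() >= 0.7 * complex_mei.activation

    def test_simple_cell_crop_activation_varies(self, simple_cell, simple_mei):
        cfg = SynthesisConfig(seed=0, **FAST_CONFIG)
        full = SubfieldMasks(m_mei=simple_mei.mask, m_v=simple_mei.mask,
                             m_f=np.zeros_like(simple_mei.mask),
                             variance_fraction=1.0)
        canvas = optimize_texture(simple_cell, full, None, cfg, n_steps=300,
                                  n_crops=8, seed=1)
        rendered = render_texture_veis(canvas, full, None, n=20, seed=2,
                                       config=cfg, model=simple_cell)
        acts = rendered.activations
        assert acts.std() / max(acts.mean(), 1e-9) > 0.3

    def test_canvas_optimization_seed_reproducible(self, complex_cell,
                                                   complex_mei):
        cfg = SynthesisConfig(seed=0, **FAST_CONFIG)
        full = SubfieldMasks(m_mei=complex_mei.mask, m_v=complex_mei.mask,
                             m_f=np.zeros_like(complex_mei.mask),
                             variance_fraction=1.0)
        a = optimize_texture(complex_cell, full, None, cfg, n_steps=30,
                             n_crops=4, seed=7)
        b = optimize_texture(complex_cell, full, None, cfg, n_steps=30,
                             n_crops=4, seed=7)
        np.testing.assert_array_equal(a.texture, b.texture)

    def test_rendered_fixed_subfield_is_identical_across_images(self,
                                                                complex_cell,
                                                                complex_mei,
                                                                complex_veis):
        cfg = SynthesisConfig(seed=0, **FAST_CONFIG)
        masks = variable_mask_series(complex_veis, complex_mei.mask,
                                     fractions=(0.3,))[0]
        fixed = masks.m_f * complex_mei.image
        canvas = optimize_texture(complex_cell, masks, fixed, cfg, n_steps=50,
                                  n_crops=4, seed=3)
        rendered = render_texture_veis(canvas, masks, fixed, n=6, seed=4,
                                       config=cfg)
        outside_v = masks.m_v <= 0
        ref = rendered.images[0][outside_v]
        for im in rendered.images[1:]:
            np.testing.assert_array_equal(im[outside_v], ref)

    def test_same_offset_gives_identical_images(self, complex_cell, complex_mei):
        cfg = SynthesisConfig(seed=0, **FAST_CONFIG)
        full = SubfieldMasks(m_mei=complex_mei.mask, m_v=complex_mei.mask,
                             m_f=np.zeros_like(complex_mei.mask),
                             variance_fraction=1.0)
        canvas = optimize_texture(complex_cell, full, None, cfg, n_steps=20,
                                  n_crops=4, seed=5)
        shape = complex_mei.image.shape
        a = canvas.crop_to_image((2, 3), shape)
        b = canvas.crop_to_image((2, 3), shape)
        np.testing.assert_array_equal(a, b)

    def test_offsets_cover_many_values(self, complex_cell, complex_mei):
        cfg = SynthesisConfig(seed=0, **FAST_CONFIG)
        full = SubfieldMasks(m_mei=complex_mei.mask, m_v=complex_mei.mask,
                             m_f=np.zeros_like(complex_mei.mask),
                             variance_fraction=1.0)
        canvas = optimize_texture(complex_cell, full, None, cfg, n_steps=10,
                                  n_crops=2, seed=5)
        rng = np.random.default_rng(0)
        offsets = canvas.random_offsets(20, rng)
        assert len(set(offsets)) >= 10


class TestHarmonicSelection:
    def test_unit_pair_selected(self):
        series = [(1.0, 1.0), (0.5, 0.9)]
        assert harmonic_selection(series) == 0

    def test_zero_distance_gives_zero_h(self):
        # member 0: H = 0 (no diversity); member 1 wins despite lower activation
        assert harmonic_selection([(1.0, 0.0), (0.6, 1.0)]) == 1

    def test_printed_toy_series_argmax_matches_brute_force(self):
        series = [(1.0, 0.4), (0.9, 0.9), (0.5, 1.0)]
        r = np.array([s[0] for s in series]) / 1.0
        d = np.array([s[1] for s in series]) / 1.0
        h = 2 * r * d / (r + d)
        assert harmonic_selection(series) == int(np.argmax(h)) == 1

    def test_all_zero_activation_rejected(self):
        with pytest.raises(ValueError):
            harmonic_selection([(0.0, 1.0), (0.0, 0.5)])


class TestBII:
    def test_constant_unit_activation_gives_one(self):
        series = [(s, 1.0) for s in np.linspace(0, 1, 8)]
        assert bipartite_invariance_index(series) == pytest.approx(1.0, abs=0.01)

    def test_linear_decay_gives_half(self):
        series = [(s, 1.0 - s) for s in np.linspace(0, 1, 9)]
        assert bipartite_invariance_index(series) == pytest.approx(0.5, abs=0.02)

    def test_spline_auc_matches_trapezoid_oracle_on_quadratic(self):
        xs = np.linspace(0, 1, 11)
        ys = 1.0 - 0.8 * xs**2
        auc = bipartite_invariance_index(list(zip(xs, ys)))
        oracle = np.trapezoid(1.0 - 0.8 * np.linspace(0, 1, 101) ** 2,
                              np.linspace(0, 1, 101))
        assert auc == pytest.approx(oracle, abs=0.02)

    def test_activation_clamped_before_integration(self):
        series = [(s, v) for s, v in zip(np.linspace(0, 1, 8),
                                         [1.4, 1.2, 1.1, 1.0, 0.9, 0.8, 0.7, 0.6])]
        assert bipartite_invariance_index(series) <= 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            bipartite_invariance_index([(0.0, 1.0), (1.0, 0.5)])


class TestPlantedBipartiteRecovery:
    def test_full_texture_never_beats_partial_at_selection(self, planted_pipeline):
        _, _, _, result, _ = planted_pipeline
        partial = result.series[result.selected_index]
        assert result.full.mean_activation_ratio <= \
            partial.mean_activation_ratio + 0.02

    def test_bii_between_simple_and_complex_regimes(self, planted_pipeline):
        _, _, _, result, _ = planted_pipeline
        assert 0.3 < result.bii < 1.0

    def test_masking_variable_subfield_lowers_activation(self, planted_pipeline):
        planted, mei, _, result, _ = planted_pipeline
        member = result.series[result.selected_index]
        manipulated = subfield_manipulation(mei, member.veis, member.masks,
                                            "mask_variable")
        orig = np.mean([planted.respond(im) for im in member.veis.images])
        ablated = np.mean([planted.respond(im) for im in manipulated])
        assert ablated < orig

    def test_variable_subfield_has_higher_median_frequency(self, planted_pipeline):
        planted, mei, _, result, _ = planted_pipeline
        member = result.series[result.selected_index]
        substituted = subfield_manipulation(
            mei, member.veis, member.masks, "swap_variable_texture",
            replacement_canvas=member.canvas, seed=1)
        # compare: content of variable subfield (texture) vs fixed subfield
        f_fixed, f_variable = subfield_median_frequency(
            [im * (member.masks.m_f > 0.3) for im in member.veis.images],
            [im * (member.masks.m_v > 0.3) for im in member.veis.images],
            deg_per_pixel=2.0)
        assert f_variable > f_fixed


class TestSubfieldManipulation:
    @pytest.fixture(scope="class")
    def member(self, complex_cell, complex_mei, complex_veis):
        cfg = SynthesisConfig(seed=0, **FAST_CONFIG)
        result = bipartite_analysis(complex_cell, complex_mei, complex_veis,
                                    fractions=(0.3, 0.45, 0.6), config=cfg,
                                    seed=5, **SCALED)
        return complex_mei, result.series[result.selected_index], result

    def test_mask_fixed_preserves_variable_pixels(self, member):
        mei, m, _ = member
        out = subfield_manipulation(mei, m.veis, m.masks, "mask_fixed")
        v_sup = m.masks.m_v > 0.3
        for orig, new in zip(m.veis.images, out):
            np.testing.assert_array_equal(new[v_sup], orig[v_sup])

    def test_swap_fixed_natural_moment_matched(self, member):
        mei, m, _ = member
        pool = naturalistic_images(10, seed=9)
        out = subfield_manipulation(mei, m.veis, m.masks, "swap_fixed_natural",
                                    replacement_pool=pool, seed=2)
        f_sup = m.masks.m_f > 0.3
        for orig, new in zip(m.veis.images, out):
            assert new[f_sup].mean() == pytest.approx(orig[f_sup].mean(),
                                                      abs=0.02)
            assert new[f_sup].std() == pytest.approx(orig[f_sup].std(),
                                                     rel=0.02)

    def test_unknown_mode_rejected(self, member):
        mei, m, _ = member
        with pytest.raises(ValueError, match="mode"):
            subfield_manipulation(mei, m.veis, m.masks, "mask_everything")


class TestControlsParameterizations:
    def test_no_spatial_division_extremes(self, complex_cell, complex_mei):
        cfg = SynthesisConfig(seed=0, **FAST_CONFIG)
        res = no_spatial_division_veis(complex_cell, complex_mei,
                                       c_grid=(0.0, 0.5, 1.0), config=cfg,
                                       n_steps=100, n_crops=4, n_render=8,
                                       seed=1)
        # c = 1 reproduces the MEI: zero diversity at the last grid point
        assert res.diversities[-1] == pytest.approx(0.0)
        assert res.activations[-1] == pytest.approx(1.0)
        # c = 0 is the full-texture model: diverse but weaker
        assert res.diversities[0] > 0

    def test_two_variable_model_varies_both_subfields(self, complex_cell,
                                                      complex_mei,
                                                      complex_veis):
        cfg = SynthesisConfig(seed=0, **FAST_CONFIG)
        series = variable_mask_series(complex_veis, complex_mei.mask,
                                      fractions=(0.4,))
        out = two_variable_veis(complex_cell, series, complex_mei, config=cfg,
                                n_steps=100, n_crops=4, n_render=8, seed=2)
        stack = np.stack(out.images)
        m = series[0]
        v_var = stack.var(axis=0)[m.m_v > 0.3].mean()
        f_var = stack.var(axis=0)[m.m_f > 0.3].mean()
        assert v_var > 0 and f_var > 0


class TestRadialFrequency:
    def test_pure_grating_median_matches_its_frequency(self):
        g = gabor_image(GaborParams(sigma=1e6, wavelength=5.0, theta=0.0),
                        (64, 64), 2.0)
        f = median_radial_frequency([g], deg_per_pixel=2.0)
        assert f == pytest.approx(0.2, rel=0.10)

    def test_white_noise_median_near_mid_nyquist(self):
        imgs = naturalistic_images(30, shape=(64, 64), spectral_exponent=0.0,
                                   seed=2, clip=None)
        f = median_radial_frequency(imgs, deg_per_pixel=2.0)
        assert f == pytest.approx(0.125, abs=0.02)

    def test_negation_invariance(self):
        img = naturalistic_images(1, seed=3)[0]
        a = median_radial_frequency([img], 2.0)
        b = median_radial_frequency([-img], 2.0)
        assert a == pytest.approx(b)

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError):
            median_radial_frequency([np.zeros((16, 16))], 2.0)
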