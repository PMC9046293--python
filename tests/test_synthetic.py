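import math

import numpy as np
import pytest

from cytoparcel import (
    AreaSpec,
    RibbonGeometry,
    generate_feature_population,
    generate_label_volumes,
    generate_section,
    generate_section_series,
    make_laminar_density,
)
from cytoparcel.synthetic import density_at_depth

UNIFORM = AreaSpec("uni", (1 / 6,) * 6, (0.5,) * 6, cell_radius_um=10.0)


class TestAreaSpec:
    def test_rejects_unnormalized_fractions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AreaSpec("bad", (0.2,) * 6, (0.5,) * 6)

    def test_rejects_density_outside_unit_interval(self):
        with pytest.raises(ValueError, match="densities"):
            AreaSpec("bad", (1 / 6,) * 6, (0.5,) * 5 + (1.2,))


class TestLaminarDensity:
    def test_uniform_spec_gives_constant_curve(self):
        curve = make_laminar_density(UNIFORM, 50)
        assert np.allclose(curve, 0.5)

    def test_single_dense_layer_forms_plateau(self):
        spec = AreaSpec("gran", (0.25, 0.25, 0.0, 0.1, 0.2, 0.2),
                        (0.3, 0.3, 0.3, 0.9, 0.3, 0.3))
        curve = make_laminar_density(spec, 1001)
        depths = np.linspace(0, 1, 1001)
        in_layer4 = (depths > 0.5) & (depths < 0.6)
        assert np.allclose(curve[in_layer4], 0.9)
        assert np.allclose(curve[depths < 0.49], 0.3)
        plateau_width = np.mean(curve > 0.6)
        assert plateau_width == pytest.approx(0.1, abs=0.01)

    def test_integral_matches_fraction_weighted_sum(self):
        spec = AreaSpec("x", (0.1, 0.15, 0.3, 0.1, 0.15, 0.2),
                        (0.2, 0.5, 0.3, 0.9, 0.4, 0.6))
        n = 20001
        curve = make_laminar_density(spec, n)
        integral = np.trapezoid(curve, dx=1.0 / (n - 1))
        expected = float(np.dot(spec.layer_fractions, spec.layer_densities))
        assert integral == pytest.approx(expected, abs=5e-4)

    def test_requires_six_samples(self):
        with pytest.raises(ValueError):
            make_laminar_density(UNIFORM, 5)


class TestGenerateSection:
    def test_single_area_has_no_borders(self, small_geometry):
        _, truth = generate_section([UNIFORM], small_geometry,
                                    pixel_size_um=2.0, seed=0)
        assert truth.border_traverse_indices == []
        assert len(set(truth.area_labels_per_traverse)) == 1

    def test_two_areas_split_at_mid_arc(self, two_areas, small_geometry):
        _, truth = generate_section(list(two_areas), small_geometry,
                                    pixel_size_um=2.0, seed=0)
        n = len(truth.area_labels_per_traverse)
        assert len(truth.border_traverse_indices) == 1
        assert truth.border_traverse_indices[0] == pytest.approx(n / 2, abs=1)

    def test_rejects_unresolvable_cells(self, small_geometry):
        with pytest.raises(ValueError, match="unresolvable"):
            generate_section([UNIFORM], small_geometry, pixel_size_um=20.0,
                             seed=0)

    def test_fixed_seed_is_bit_identical(self, small_geometry):
        a, _ = generate_section([UNIFORM], small_geometry, 2.0, seed=5)
        b, _ = generate_section([UNIFORM], small_geometry, 2.0, seed=5)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.outer_contour, b.outer_contour)

    @pytest.mark.parametrize("thickness_um,tol", [(250.0, 0.08), (500.0, 0.05)])
    def test_empirical_layer_density_matches_spec(self, thickness_um, tol):
        """Observed per-layer cell-area fraction converges to the spec."""
        spec = AreaSpec("d3", (1 / 6,) * 6, (0.3, 0.2, 0.4, 0.3, 0.25, 0.35),
                        cell_radius_um=10.0)
        geo = RibbonGeometry(outer_radius_um=4000.0, thickness_um=thickness_um,
                             arc_deg=30.0, traverse_spacing_um=16.0)
        sec, _ = generate_section([spec], geo, pixel_size_um=1.0, seed=3)
        h, w = sec.mask.shape
        yy, xx = np.mgrid[0:h, 0:w]
        # geometry is known analytically: recover center from the contours
        r_out = 4000.0
        r_in = r_out - thickness_um
        cx = sec.outer_contour[:, 0].max() - r_out
        cy = (sec.outer_contour[0, 1] + sec.outer_contour[-1, 1]) / 2
        rr = np.hypot(xx - cx, yy - cy)
        ang = np.arctan2(yy - cy, xx - cx)
        half = math.radians(geo.arc_deg) / 2
        depth = (r_out - rr) / (r_out - r_in)
        margin_d = spec.cell_radius_um / thickness_um
        inside = (rr > r_in) & (rr < r_out) & (np.abs(ang) < half * 0.9)
        for k in range(6):
            lo, hi = k / 6 + margin_d, (k + 1) / 6 - margin_d
            layer = inside & (depth > lo) & (depth < hi)
            emp = sec.mask[layer].mean()
            assert emp == pytest.approx(spec.layer_densities[k], abs=tol)


class TestSectionSeries:
    def test_zero_drift_keeps_border_fixed(self, two_areas, small_geometry):
        series = generate_section_series(3, list(two_areas), small_geometry,
                                         2.0, border_drift_traverses=0, seed=1)
        idx = [t.border_traverse_indices[0] for _, t in series]
        assert len(set(idx)) == 1

    def test_drift_is_bounded(self, two_areas, small_geometry):
        series = generate_section_series(5, list(two_areas), small_geometry,
                                         2.0, border_drift_traverses=2, seed=2)
        idx = [t.border_traverse_indices[0] for _, t in series]
        assert max(idx) - min(idx) <= 4  # each section within +/-2 of base

    def test_rejects_fewer_than_three_sections(self, two_areas, small_geometry):
        with pytest.raises(ValueError, match="at least 3"):
            generate_section_series(2, list(two_areas), small_geometry, 2.0,
                                    border_drift_traverses=0, seed=0)


def _base_labels() -> np.ndarray:
    base = np.zeros((32, 32, 32), np.int32)
    base[4:12, 8:20, 8:20] = 1
    base[18:28, 8:20, 8:20] = 2
    return base


class TestLabelVolumes:
    def test_zero_jitter_reproduces_base(self):
        base = _base_labels()
        vols = generate_label_volumes(10, base, jitter_vox=0, seed=0)
        assert len(vols) == 10
        for v in vols:
            assert np.array_equal(v.data, base)

    def test_labels_stay_mutually_exclusive(self):
        vols = generate_label_volumes(8, _base_labels(), jitter_vox=3, seed=1)
        for v in vols:
            assert set(np.unique(v.data)) <= {0, 1, 2}

    def test_overlap_decreases_with_jitter(self):
        base = _base_labels()
        mean_dice = []
        for jit in (0, 2, 5):
            vols = generate_label_volumes(10, base, jitter_vox=jit, seed=7)
            masks = [v.data == 1 for v in vols]
            dices = [
                2 * np.sum(a & b) / (a.sum() + b.sum())
                for i, a in enumerate(masks) for b in masks[i + 1:]
            ]
            mean_dice.append(np.mean(dices))
        assert mean_dice[0] == pytest.approx(1.0)
        assert mean_dice[0] > mean_dice[1] > mean_dice[2]


class TestFeaturePopulation:
    def test_rejects_non_spd_covariance(self):
        cov = -np.eye(3)
        with pytest.raises(ValueError, match="positive definite"):
            generate_feature_population([np.zeros(3)], cov, 5, seed=0)

    def test_empty_output_for_zero_samples(self):
        x, y = generate_feature_population([np.zeros(4)], np.eye(4), 0, seed=0)
        assert x.shape == (0, 4) and y.size == 0

    def test_planted_mahalanobis_separation(self):
        """Means 5 pooled SDs apart give sample D^2 near 25."""
        from cytoparcel import mahalanobis_d2

        m2 = np.zeros(10)
        m2[0] = 5.0
        x, y = generate_feature_population([np.zeros(10), m2], np.eye(10),
                                           n_per_group=400, seed=9)
        d2 = mahalanobis_d2(x[y == 0], x[y == 1])
        assert d2 == pytest.approx(25.0, rel=0.15)

    def test_reproducible_under_seed(self):
        a, _ = generate_feature_population([np.zeros(3)], np.eye(3), 7, seed=4)
        b, _ = generate_feature_population([np.zeros(3)], np.eye(3), 7, seed=4)
        assert np.array_equal(a, b)
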