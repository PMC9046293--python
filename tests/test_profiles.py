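import numpy as np
import pytest

from cytoparcel import (
    compute_features,
    compute_gli,
    compute_traverses,
    extract_profile,
    make_laminar_density,
)
from cytoparcel.gli import GliImage
from cytoparcel.profiles import FEATURE_NAMES, Traverse
from cytoparcel.synthetic import density_at_depth


def _arc(radius, theta0, theta1, center, n=400):
    th = np.linspace(theta0, theta1, n)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


class TestTraverses:
    def test_parallel_contours_give_perpendicular_equal_traverses(self):
        outer = np.column_stack([np.linspace(0, 300, 200),
                                 np.full(200, 10.0)])
        inner = np.column_stack([np.linspace(0, 300, 200),
                                 np.full(200, 110.0)])
        trs = compute_traverses(outer, inner, spacing_um=20.0)
        lens = np.array([t.arc_length for t in trs])
        assert np.all(np.abs(lens - 100.0) < 3.0)
        # perpendicular: endpoint x stays close to seed x
        for t in trs[2:-2]:
            assert abs(t.points[-1, 0] - t.points[0, 0]) < 3.0

    def test_concentric_arcs_give_radial_traverses(self):
        c = (10.0, 260.0)
        outer = _arc(300.0, -0.8, 0.8, c)
        inner = _arc(200.0, -0.8, 0.8, c)
        trs = compute_traverses(outer, inner, spacing_um=16.0)
        lens = np.array([t.arc_length for t in trs])
        assert np.all(np.abs(lens - 100.0) < 3.0)
        mid = trs[len(trs) // 2]
        d = mid.points[-1] - mid.points[0]
        radial = mid.points[0] - np.array(c)
        cosang = abs(np.dot(d, radial) / np.linalg.norm(d) / np.linalg.norm(radial))
        assert cosang > 0.99

    def test_traverse_count_matches_arc_length(self):
        c = (0.0, 0.0)
        outer = _arc(300.0, -0.5, 0.5, c, n=2000)
        inner = _arc(220.0, -0.5, 0.5, c, n=2000)
        arc = np.sum(np.hypot(*np.diff(outer, axis=0).T))
        trs = compute_traverses(outer, inner, spacing_um=16.0)
        assert len(trs) == int(arc / 16.0) + 1

    def test_traverses_do_not_cross(self):
        """Streamlines of the harmonic field stay ordered along the ribbon."""
        c = (10.0, 260.0)
        outer = _arc(300.0, -0.7, 0.7, c)
        inner = _arc(210.0, -0.7, 0.7, c)
        trs = compute_traverses(outer, inner, spacing_um=12.0)
        # at several depths, angular position must be strictly increasing
        for frac in (0.25, 0.5, 0.75):
            angles = []
            for t in trs:
                k = int(frac * (len(t.points) - 1))
                p = t.points[k] - np.array(c)
                angles.append(np.arctan2(p[1], p[0]))
            assert np.all(np.diff(angles) > 0)

    def test_crossing_contours_rejected(self):
        outer = np.array([[0.0, 0.0], [100.0, 50.0]])
        inner = np.array([[0.0, 50.0], [100.0, 0.0]])
        with pytest.raises(ValueError, match="cross|ribbon"):
            compute_traverses(outer, inner, spacing_um=10.0)


class TestExtractProfile:
    def test_constant_gli_gives_constant_profile(self):
        g = GliImage(np.full((20, 20), 0.37), 16.0, 1.0)
        t = Traverse(np.array([[80.0, 10.0], [80.0, 300.0]]), 0)
        prof = extract_profile(g, t, n_depth=51)
        assert np.allclose(prof.samples, 0.37)

    def test_linear_gli_gives_linear_profile(self):
        vals = np.tile(np.linspace(0, 1, 30)[:, None], (1, 10))
        g = GliImage(vals, 16.0, 1.0)  # varies along y
        t = Traverse(np.array([[80.0, 8.0], [80.0, 470.0]]), 0)
        prof = extract_profile(g, t, n_depth=101)
        resid = prof.samples - np.polyval(
            np.polyfit(np.arange(101), prof.samples, 1), np.arange(101))
        assert np.max(np.abs(resid)) < 1e-3

    def test_traverse_outside_grid_rejected(self):
        g = GliImage(np.zeros((5, 5)), 16.0, 1.0)
        t = Traverse(np.array([[0.0, 0.0], [500.0, 0.0]]), 0)
        with pytest.raises(ValueError, match="exits"):
            extract_profile(g, t, 11)

    def test_profile_plateaus_match_generator_truth(self, laminar_section,
                                                    two_areas):
        """Mid-layer profile values agree with the planted laminar density."""
        section, truth = laminar_section
        g = compute_gli(section, 16.0)
        trs = compute_traverses(section.outer_contour, section.inner_contour,
                                16.0, section.pixel_size_um)
        b = truth.border_traverse_indices[0]
        # average profiles well inside the first area to beat Poisson noise
        profs = [extract_profile(g, t, 101).samples
                 for t in trs[5:b - 5]]
        mean_prof = np.mean(profs, axis=0)
        depths = np.linspace(0, 1, 101)
        expected = density_at_depth(two_areas[0], depths)
        # compare in mid-layer windows, away from layer boundaries
        bounds = two_areas[0].boundaries
        for k in range(1, 6):  # layer I sits at the tissue edge; skip it
            mid = (bounds[k] + bounds[k + 1]) / 2
            win = np.abs(depths - mid) < 0.03
            assert np.mean(mean_prof[win]) == pytest.approx(
                np.mean(expected[win]), abs=0.07)


class TestFeatures:
    def test_constant_profile(self):
        f = compute_features(np.full(101, 0.42))
        assert f[0] == pytest.approx(0.42)
        assert f[1] == pytest.approx(50.0)
        # zero derivative mass -> degenerate convention for features 6-10
        assert np.allclose(f[5:], [0.0, 50.0, 0.0, 0.0, 0.0])

    def test_all_zero_profile_convention(self):
        f = compute_features(np.zeros(101))
        assert np.allclose(f, [0, 50, 0, 0, 0, 0, 50, 0, 0, 0])

    def test_mirror_reflection_property(self, rng):
        g = rng.random(101) * 0.5 + 0.1
        f = compute_features(g)
        fm = compute_features(g[::-1])
        names = dict(zip(FEATURE_NAMES, range(10)))
        assert fm[names["mean_amplitude"]] == pytest.approx(f[0])
        assert fm[names["centroid_depth"]] == pytest.approx(100 - f[1])
        assert fm[names["depth_sd"]] == pytest.approx(f[2])
        assert fm[names["depth_skewness"]] == pytest.approx(-f[3])
        assert fm[names["depth_kurtosis"]] == pytest.approx(f[4])
        assert fm[names["deriv_centroid_depth"]] == pytest.approx(100 - f[6])
        assert fm[names["deriv_depth_skewness"]] == pytest.approx(-f[8])

    def test_narrowing_spike_concentrates_moments(self):
        depths = np.linspace(0, 100, 1001)
        sds = []
        for width in (8.0, 4.0, 2.0):
            g = np.exp(-0.5 * ((depths - 30) / width) ** 2)
            f = compute_features(g)
            assert f[1] == pytest.approx(30.0, abs=0.5)
            sds.append(f[2])
        assert sds[0] > sds[1] > sds[2]

    def test_invariant_to_depth_resampling(self):
        depths = np.linspace(0, 100, 101)
        g = 0.4 + 0.2 * np.sin(depths / 15.0)
        f1 = compute_features(g)
        g2 = 0.4 + 0.2 * np.sin(np.linspace(0, 100, 201) / 15.0)
        f2 = compute_features(g2)
        assert np.allclose(f1, f2, rtol=1e-6, atol=1e-9)

    def test_amplitude_scaling(self):
        g = np.abs(np.sin(np.linspace(0, 3, 101))) + 0.1
        f1 = compute_features(g)
        f3 = compute_features(3.0 * g)
        assert f3[0] == pytest.approx(3 * f1[0])
        assert f3[5] == pytest.approx(3 * f1[5])
        # weighted depth moments are amplitude-scale invariant
        assert np.allclose(f3[1:5], f1[1:5])
        assert np.allclose(f3[6:], f1[6:])

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            compute_features(np.array([0.1, 0.2]))
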