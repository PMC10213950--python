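"""Hue-saturation discrimination, tolerance ellipses, ratio line, MFI/LOD/TBR."""

import colorsys

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hexachrome import (
    HueSatPoint,
    Region,
    SceneSpec,
    ValidationError,
    clusters_separable,
    estimate_ratio,
    fit_ratio_line,
    fit_tolerance_ellipse,
    limit_of_detection,
    make_vial_scene,
    nir_to_huesat,
    roi_mfi,
    tumor_background_ratio,
)
from hexachrome.spectral import RatioLine, SAT_SCALE


class TestHueSat:
    def test_equal_channels_are_gray(self):
        pt = nir_to_huesat([5.0, 5.0, 5.0])
        assert pt.sat == 0.0 and pt.valid

    def test_pure_bottom_is_pseudo_red(self):
        pt = nir_to_huesat([0.0, 0.0, 7.0])  # (top, middle, bottom)
        assert pt.hue == pytest.approx(0.0) and pt.sat == pytest.approx(1.0)

    def test_all_zero_flags_undefined_hue(self):
        pt = nir_to_huesat([0.0, 0.0, 0.0])
        assert not pt.valid

    def test_negative_triplet_rejected(self):
        with pytest.raises(ValidationError):
            nir_to_huesat([1.0, -0.1, 2.0])

    @given(
        t=st.tuples(*[st.floats(0.01, 1e6) for _ in range(3)]),
        k=st.floats(1e-6, 1e6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariance(self, t, k):
        """The ratio-metric property: positive scaling leaves hue/sat fixed."""
        a = nir_to_huesat(np.asarray(t))
        b = nir_to_huesat(k * np.asarray(t))
        assert abs(a.hue - b.hue) < 1e-9 or abs(abs(a.hue - b.hue) - 360) < 1e-9
        assert a.sat == pytest.approx(b.sat, abs=1e-12)

    def test_matches_colorsys_oracle(self, rng):
        triplets = rng.uniform(0, 100, size=(500, 3))
        pts = nir_to_huesat(triplets)
        for i, (top, mid, bot) in enumerate(triplets):
            h, s, _ = colorsys.rgb_to_hsv(bot / 100, mid / 100, top / 100)
            assert pts.hue[i] == pytest.approx((h * 360) % 360, abs=1e-8)
            assert pts.sat[i] == pytest.approx(s, abs=1e-12)


class TestRoiMfi:
    def test_uniform_plane(self):
        assert roi_mfi(np.full((5, 5), 3.5), np.ones((5, 5), bool)) == 3.5

    def test_single_pixel_mask(self):
        plane = np.arange(16.0).reshape(4, 4)
        mask = np.zeros((4, 4), bool)
        mask[2, 3] = True
        assert roi_mfi(plane, mask) == plane[2, 3]

    def test_matches_scalar_accumulator(self, rng):
        plane = rng.normal(size=(9, 9))
        mask = rng.random((9, 9)) > 0.4
        acc, n = 0.0, 0
        for r in range(9):
            for c in range(9):
                if mask[r, c]:
                    acc += plane[r, c]
                    n += 1
        assert roi_mfi(plane, mask) == pytest.approx(acc / n)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            roi_mfi(np.ones((3, 3)), np.zeros((3, 3), bool))


def lod_oracle(series, background):
    """Exhaustive-scan reference implementation."""
    bg = np.asarray(background, float)
    thr = bg.mean() + 2 * bg.std(ddof=1)
    candidates = []
    for i, (conc, mfis) in enumerate(series):
        if all(np.mean(m) > thr for _, m in series[i:]):
            candidates.append(conc)
    return min(candidates) if candidates else None


class TestLimitOfDetection:
    # background replicates with mean 73.09 and SD 0.09
    BACKGROUND = [73.00, 73.09, 73.18]

    def test_dilution_series_with_crossing_at_point_one(self):
        bg = np.asarray(self.BACKGROUND)
        assert bg.mean() == pytest.approx(73.09)
        assert bg.std(ddof=1) == pytest.approx(0.09)
        # signal calibrated so only >= 0.1 uM clears mean + 2 SD = 73.27
        series = [
            (c, [73.09 + 3.0 * c - 0.01, 73.09 + 3.0 * c, 73.09 + 3.0 * c + 0.01])
            for c in (0.025, 0.05, 0.1, 0.2, 0.4, 1.0)
        ]
        assert limit_of_detection(series, self.BACKGROUND) == pytest.approx(0.1)

    def test_never_exceeding_series_returns_none(self):
        series = [(c, [73.0, 73.1]) for c in (0.1, 0.5, 1.0)]
        assert limit_of_detection(series, self.BACKGROUND) is None

    def test_matches_exhaustive_oracle_on_random_series(self, rng):
        for _ in range(300):
            concs = np.sort(rng.uniform(0.01, 1.0, size=rng.integers(2, 8)))
            concs = np.unique(concs)
            series = [
                (float(c), list(rng.normal(73.0 + rng.uniform(-1, 3) * c, 0.2, 3)))
                for c in concs
            ]
            bg = list(rng.normal(73.0, 0.2, 3))
            assert limit_of_detection(series, bg) == lod_oracle(series, bg)

    def test_unsorted_series_rejected(self):
        with pytest.raises(ValidationError):
            limit_of_detection([(0.5, [80]), (0.1, [90])], self.BACKGROUND)


class TestToleranceEllipse:
    def test_chi2_axes_on_isotropic_gaussian(self, rng):
        pts = rng.normal(size=(200_000, 2))
        ell = fit_tolerance_ellipse(pts[:, 0] % 360, (pts[:, 1] + 50) / SAT_SCALE, 0.95)
        vals = np.linalg.eigvalsh(ell.covariance)
        semi_axes = np.sqrt(vals * ell.scale)
        np.testing.assert_allclose(semi_axes, np.sqrt(5.991), rtol=0.02)

    def test_identical_points_give_degenerate_zero_area(self):
        ell = fit_tolerance_ellipse([10.0] * 5, [0.5] * 5, 0.95)
        assert ell.degenerate
        assert np.linalg.eigvalsh(ell.covariance)[0] == pytest.approx(0.0, abs=1e-12)

    def test_hue_wrap_does_not_inflate_covariance(self, rng):
        """A tight cluster straddling 0/360 must not appear 360 deg wide."""
        hues = (rng.normal(0, 1.0, 500)) % 360.0
        sats = rng.normal(0.8, 0.01, 500)
        ell = fit_tolerance_ellipse(hues, sats, 0.95)
        assert max(np.linalg.eigvalsh(ell.covariance)) < 10.0
        assert ell.center[0] < 5 or ell.center[0] > 355

    def test_coverage_of_95_ellipse(self, rng):
        pts = rng.multivariate_normal([20, 60], [[4, 1.5], [1.5, 2]], size=10_000)
        ell = fit_tolerance_ellipse(pts[:, 0], pts[:, 1] / SAT_SCALE, 0.95)
        inside = ell.contains(pts[:, 0], pts[:, 1] / SAT_SCALE)
        assert 0.94 <= inside.mean() <= 0.96

    def test_invalid_level_rejected(self):
        with pytest.raises(ValidationError):
            fit_tolerance_ellipse([1, 2, 3], [0.1, 0.2, 0.3], 1.5)


def grid_overlap_oracle(a, b, n=400):
    """Dense-grid check for interior intersection of two ellipses."""
    pts = np.concatenate([a.boundary(256), b.boundary(256)])
    h0, h1 = pts[:, 0].min(), pts[:, 0].max()
    s0, s1 = pts[:, 1].min(), pts[:, 1].max()
    hh, ss = np.meshgrid(np.linspace(h0, h1, n), np.linspace(s0, s1, n))
    both = (a.mahalanobis2(hh, ss) < a.scale) & (b.mahalanobis2(hh, ss) < b.scale)
    return bool(both.any())


class TestSeparability:
    def ellipse(self, center, cov, level=0.95):
        import scipy.stats

        return __import__("hexachrome").ToleranceEllipse(
            center=center,
            covariance=np.asarray(cov, float),
            level=level,
            scale=float(scipy.stats.chi2.ppf(level, 2)),
        )

    def test_identical_ellipses_overlap(self):
        e = self.ellipse((10, 50), [[1, 0], [0, 1]])
        assert clusters_separable(e, e) is False

    def test_distant_ellipses_separable(self):
        a = self.ellipse((10, 50), [[1, 0], [0, 1]])
        b = self.ellipse((100, 50), [[1, 0], [0, 1]])
        assert clusters_separable(a, b) is True

    def test_agrees_with_grid_oracle_near_the_boundary(self, rng):
        for _ in range(50):
            c1 = (rng.uniform(0, 30), rng.uniform(40, 60))
            d = rng.uniform(2.0, 8.0)
            c2 = (c1[0] + d, c1[1] + rng.uniform(-2, 2))
            def rand_cov():
                a = rng.uniform(0.5, 2.0, size=(2, 2))
                return a @ a.T + 0.1 * np.eye(2)
            a = self.ellipse(c1, rand_cov())
            b = self.ellipse(c2, rand_cov())
            assert clusters_separable(a, b) == (not grid_overlap_oracle(a, b))

    def test_mismatched_levels_rejected(self):
        a = self.ellipse((0, 50), np.eye(2), 0.95)
        b = self.ellipse((5, 50), np.eye(2), 0.68)
        with pytest.raises(ValidationError):
            clusters_separable(a, b)


def hs(hue, sat):
    return HueSatPoint(hue, sat, True)


class TestRatioLine:
    def test_collinear_means_interpolated_exactly(self):
        means = {f: hs(10 + 5 * f, 0.8 - 0.1 * f) for f in (0.0, 0.25, 0.5, 0.75, 1.0)}
        line = fit_ratio_line(means)
        assert line.residual == pytest.approx(0.0, abs=1e-9)
        for f, pt in means.items():
            assert estimate_ratio(pt, line) == pytest.approx(f, abs=1e-9)

    def test_two_points_define_the_line(self):
        line = fit_ratio_line({0.0: hs(9.0, 0.88), 1.0: hs(14.0, 0.80)})
        assert estimate_ratio(hs(9.0, 0.88), line) == pytest.approx(0.0, abs=1e-12)
        assert estimate_ratio(hs(14.0, 0.80), line) == pytest.approx(1.0, abs=1e-12)

    def test_tls_residual_matches_angle_grid_search(self, rng):
        means = {
            f: hs(10 + 5 * f + rng.normal(0, 0.3), 0.85 - 0.08 * f + rng.normal(0, 0.005))
            for f in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
        }
        line = fit_ratio_line(means)
        pts = np.array([[p.hue, p.sat * SAT_SCALE] for p in means.values()])
        centred = pts - pts.mean(axis=0)
        best = np.inf
        for theta in np.linspace(0, np.pi, 20001):
            d = np.array([np.cos(theta), np.sin(theta)])
            resid = np.sum(centred**2) - np.sum((centred @ d) ** 2)
            best = min(best, resid)
        assert line.residual**2 == pytest.approx(best, rel=1e-4, abs=1e-9)

    def test_coincident_pure_means_rejected(self):
        with pytest.raises(ValidationError, match="indistinguishable"):
            fit_ratio_line({0.0: hs(10, 0.8), 1.0: hs(10, 0.8)})

    def test_missing_endpoint_rejected(self):
        with pytest.raises(ValidationError):
            fit_ratio_line({0.2: hs(10, 0.8), 1.0: hs(14, 0.7)})

    def test_gray_point_rejected(self):
        line = fit_ratio_line({0.0: hs(9.0, 0.88), 1.0: hs(14.0, 0.80)})
        with pytest.raises(ValidationError):
            estimate_ratio(HueSatPoint(0.0, 0.0, False), line)

    def test_json_round_trip(self):
        line = fit_ratio_line({0.0: hs(9.0, 0.88), 0.5: hs(11.2, 0.84), 1.0: hs(14.0, 0.80)})
        back = RatioLine.from_json(line.to_json())
        assert estimate_ratio(hs(11.0, 0.85), back) == pytest.approx(
            estimate_ratio(hs(11.0, 0.85), line)
        )


class TestTumorBackgroundRatio:
    def masks(self):
        t = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        t[:4], b[4:] = True, True
        return t, b

    def test_uniform_arithmetic(self):
        t, b = self.masks()
        plane = np.where(t, 450.0, 100.0)
        assert tumor_background_ratio(plane, t, b) == pytest.approx(4.5)

    def test_identical_regions_give_unity(self):
        t, b = self.masks()
        assert tumor_background_ratio(np.full((8, 8), 99.0), t, b) == pytest.approx(1.0)

    def test_generator_round_trip_recovers_contrast(self, qe, config):
        """A phantom built with a known tumour/background emission contrast
        yields a TBR close to that contrast."""
        from hexachrome import demosaic_frame, expose

        contrast = 4.0
        bg = Region(name="tissue", geometry={"kind": "background"}, mix={"ICG": 0.1})
        tum = Region(
            name="tumor", geometry={"kind": "disk", "center": (12, 12), "radius": 6},
            mix={"ICG": 0.1 * contrast},
        )
        spec = SceneSpec(shape=(24, 24), regions=(bg, tum), illumination={"785": 150.0})
        scene = make_vial_scene(spec)
        frame = expose(scene, qe, config, seed=9)
        nir = demosaic_frame(frame).nir[..., 2]
        masks = scene.ground_truth["masks"]
        tbr = tumor_background_ratio(nir, masks["tumor"], masks["tissue"])
        assert tbr == pytest.approx(contrast, rel=0.1)

    def test_overlapping_masks_rejected(self):
        t, _ = self.masks()
        with pytest.raises(ValidationError):
            tumor_background_ratio(np.ones((8, 8)), t, t)

    def test_nonpositive_background_rejected(self):
        t, b = self.masks()
        with pytest.raises(ValidationError):
            tumor_background_ratio(np.where(t, 5.0, 0.0), t, b)
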