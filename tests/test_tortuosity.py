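"""Orientation scores, exponential-curve curvature, weighted tortuosity."""

import numpy as np
import pytest
from scipy import ndimage

from retitort.core import FundusImage
from retitort.graph import VesselSegment
from retitort.tortuosity import (
    CurvatureProfile,
    estimate_theta,
    fit_local_curvature,
    lift_orientation_score,
    oracle_curvature,
    overall_tortuosity,
    segment_curvature_profile,
)

from conftest import make_bar_scene, make_ring_scene


def make_profile(kappa, confidence, av="artery", hier="branch"):
    n = len(kappa)
    return CurvatureProfile(
        points=np.zeros((n, 2)),
        kappa=np.asarray(kappa, float),
        confidence=np.asarray(confidence, float),
        theta_star=np.zeros(n),
        reliable=np.ones(n, bool),
        av_label=av,
        hierarchy_label=hier,
    )


class TestLift:
    def test_bar_at_zero_degrees_peaks_in_zero_bin(self):
        sc = make_bar_scene(theta=0.0)
        score = lift_orientation_score(sc.image, invert=True)
        vals = score.U[128, 128, :]
        assert np.argmax(vals) == 0

    def test_constant_image_lifts_to_zero(self):
        img = FundusImage(np.full((128, 128), 5.0))
        score = lift_orientation_score(img)
        assert np.abs(score.U).max() < 1e-6 * 5.0

    def test_rotating_scene_by_one_bin_shifts_planes(self):
        """Equivariance: U of the rotated scene is the cyclic shift of U."""
        nt = 16
        theta0 = 0.3
        shift = np.pi / nt
        sa = make_bar_scene(theta=theta0, size=(300, 300), length=220)
        sb = make_bar_scene(theta=theta0 + shift, size=(300, 300), length=220)
        Ua = lift_orientation_score(sa.image, n_theta=nt, invert=True)
        Ub = lift_orientation_score(sb.image, n_theta=nt, invert=True)
        tline = np.linspace(-80, 80, 60)
        offs = np.linspace(-6, 6, 9)

        def samples(theta, U):
            u = np.array([np.sin(theta), np.cos(theta)])
            nv = np.array([np.cos(theta), -np.sin(theta)])
            pts = (
                np.array([150.0, 150.0])[None, None, :]
                + tline[:, None, None] * u
                + offs[None, :, None] * nv
            ).reshape(-1, 2)
            return np.stack(
                [ndimage.map_coordinates(U[..., k], pts.T, order=1) for k in range(nt)],
                axis=1,
            )

        va = samples(theta0, Ua.U)
        vb = samples(theta0 + shift, Ub.U)
        err = np.abs(np.roll(vb, -1, axis=1) - va).mean()
        assert err < 0.02 * np.abs(va).max()

    def test_parameter_validation(self):
        img = FundusImage(np.zeros((128, 128)))
        with pytest.raises(ValueError):
            lift_orientation_score(img, n_theta=4)
        with pytest.raises(ValueError, match="aperture"):
            lift_orientation_score(img, n_theta=16, angular_aperture=0.5 * np.pi / 16)
        with pytest.raises(ValueError):
            lift_orientation_score(FundusImage(np.zeros((32, 32))))

    def test_estimate_theta_on_oblique_bar(self):
        theta = np.deg2rad(40)
        sc = make_bar_scene(theta=theta)
        score = lift_orientation_score(sc.image, invert=True)
        est = estimate_theta(score, np.array([[128.0, 128.0]]))[0]
        err = abs((est - theta + np.pi / 2) % np.pi - np.pi / 2)
        assert err < np.pi / 16  # within one theta bin


class TestCurvatureFit:
    def test_straight_bar_fits_zero_curvature(self):
        sc = make_bar_scene(theta=0.2)
        score = lift_orientation_score(sc.image, invert=True)
        prof = segment_curvature_profile(score, sc.truth_graph.segments[0], stride=2)
        interior = prof.reliable
        # within one fine-grid step of zero
        assert np.median(prof.kappa[interior]) < 1.5e-3

    @pytest.mark.parametrize("R", [50, 80, 120])
    def test_ring_curvature_within_ten_percent(self, R):
        sc = make_ring_scene(R)
        score = lift_orientation_score(sc.image, invert=True)
        prof = segment_curvature_profile(score, sc.truth_graph.segments[0], stride=2)
        med = np.median(prof.kappa[prof.reliable])
        assert med == pytest.approx(1.0 / R, rel=0.10)

    def test_background_confidence_negligible(self):
        sc = make_bar_scene(theta=0.0)
        score = lift_orientation_score(sc.image, invert=True)
        prof = segment_curvature_profile(score, sc.truth_graph.segments[0], stride=2)
        on_conf = np.median(prof.confidence[prof.reliable])
        bg_pts = np.array([[40.0, 200.0], [200.0, 40.0], [60.0, 60.0]])
        theta = estimate_theta(score, bg_pts)
        _, bg_conf, _ = fit_local_curvature(score, bg_pts, theta)
        assert bg_conf.max() < 0.05 * on_conf

    def test_point_near_border_flagged_unreliable(self):
        sc = make_bar_scene(theta=0.0)
        score = lift_orientation_score(sc.image, invert=True)
        pts = np.array([[3.0, 128.0]])
        _, conf, reliable = fit_local_curvature(score, pts, np.array([0.0]))
        assert not reliable[0]
        assert conf[0] == 0.0


class TestOverallTortuosity:
    def test_constant_curvature_returns_that_constant(self):
        res = overall_tortuosity([make_profile([2e-3] * 3, [0.5, 1.0, 2.0])])
        assert res["branch_artery"].tau == pytest.approx(2e-3)

    def test_weighted_mean_arithmetic(self):
        res = overall_tortuosity(
            [make_profile([1e-3, 2e-3, 3e-3], [1.0, 1.0, 2.0])]
        )
        assert res["branch_artery"].tau == pytest.approx(2.25e-3)
        assert res["branch_artery"].tau_scaled == pytest.approx(22.5)

    def test_zero_confidence_flagged_missing_not_zero(self):
        res = overall_tortuosity([make_profile([1e-3, 2e-3], [0.0, 0.0])])
        r = res["branch_artery"]
        assert r.missing and r.tau is None

    def test_absent_class_flagged_missing(self):
        res = overall_tortuosity([make_profile([1e-3], [1.0], av="vein", hier="main")])
        assert res["branch_artery"].missing
        assert not res["main_vein"].missing

    def test_pooling_across_vessels_of_one_class(self):
        a = make_profile([1e-3], [1.0])
        b = make_profile([3e-3], [3.0])
        res = overall_tortuosity([a, b])
        assert res["branch_artery"].tau == pytest.approx((1e-3 + 9e-3) / 4.0)
        assert res["branch_artery"].n_points == 2


class TestOracle:
    def test_straight_line_is_flat(self):
        pts = np.stack([np.full(60, 10.0), np.linspace(0, 120, 60)], axis=1)
        assert oracle_curvature(pts).max() < 1e-8

    def test_circle_closed_form(self):
        t = np.linspace(0, np.pi, 300)
        pts = np.stack([100 + 100 * np.cos(t), 100 + 100 * np.sin(t)], axis=1)
        k = oracle_curvature(pts)
        assert np.allclose(k[30:-30], 0.01, atol=1e-4)

    def test_sinusoid_matches_closed_form(self):
        x = np.linspace(0, 300, 400)
        A, lam = 10.0, 100.0
        w = 2 * np.pi / lam
        y = A * np.sin(w * x)
        k = oracle_curvature(np.stack([y + 50, x], axis=1))
        k_true = np.abs(-A * w**2 * np.sin(w * x)) / (1 + (A * w * np.cos(w * x)) ** 2) ** 1.5
        m = slice(30, -30)
        assert np.all(np.abs(k[m] - k_true[m]) <= 0.02 * np.maximum(k_true[m], 5e-4))

    def test_degenerate_inputs_rejected(self):
        pts = np.zeros((10, 2))
        with pytest.raises(ValueError, match="repeated"):
            oracle_curvature(pts)
        with pytest.raises(ValueError, match="7"):
            oracle_curvature(np.stack([np.arange(5.0), np.arange(5.0)], axis=1))
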