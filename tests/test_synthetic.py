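"""Synthetic fundus generator: path geometry, rendering, cohorts."""

import warnings

import numpy as np
import pytest

from retitort.core import GROUPS, REPORT_CLASSES, dice
from retitort.graph import rasterize_graph
from retitort.synthetic import (
    CohortSpec,
    VesselPathSpec,
    default_cohort_spec,
    demo_cohort_spec,
    generate_vessel_path,
    render_scene,
    simulate_cohort,
    sinusoid_amplitude_for_curvature,
    sinusoid_mean_curvature,
)


def fd_mean_curvature(amplitude, wavelength, length, step=0.01):
    """Independent oracle: dense finite-difference curvature of the sinusoid."""
    t = np.arange(0, 1.2 * length, step)
    x, y = t, amplitude * np.sin(2 * np.pi * t / wavelength)
    dx, dy = np.gradient(x, step), np.gradient(y, step)
    ddx, ddy = np.gradient(dx, step), np.gradient(dy, step)
    kappa = np.abs(dx * ddy - dy * ddx) / (dx**2 + dy**2) ** 1.5
    ds = np.sqrt(dx**2 + dy**2)
    s = np.cumsum(ds * step)
    keep = s <= length
    return np.sum(kappa[keep] * ds[keep]) / np.sum(ds[keep])


class TestVesselPath:
    def test_straight_line_has_zero_curvature(self):
        sp = VesselPathSpec("straight", length_px=200, radius_px=3)
        pts, kappa = generate_vessel_path(sp, step_px=1.0)
        assert kappa == 0.0
        assert len(pts) == 201

    def test_arc_curvature_is_inverse_radius(self):
        sp = VesselPathSpec(
            "circular_arc", length_px=200, radius_px=3, arc_radius_px=100
        )
        _, kappa = generate_vessel_path(sp, step_px=1.0)
        assert kappa == pytest.approx(0.01, rel=1e-9)

    def test_sinusoid_curvature_matches_finite_difference_oracle(self):
        sp = VesselPathSpec(
            "sinusoid", length_px=300, radius_px=3, amplitude_px=10, wavelength_px=100
        )
        _, kappa = generate_vessel_path(sp, step_px=1.0)
        oracle = fd_mean_curvature(10, 100, 300)
        assert kappa == pytest.approx(oracle, rel=1e-3)

    @pytest.mark.parametrize("family,kwargs", [
        ("circular_arc", {"arc_radius_px": 100}),
        ("sinusoid", {"amplitude_px": 10, "wavelength_px": 100}),
        ("straight", {}),
    ])
    def test_uniform_arc_step(self, family, kwargs):
        sp = VesselPathSpec(family, length_px=150, radius_px=3, **kwargs)
        pts, _ = generate_vessel_path(sp, step_px=1.5)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.all(np.abs(steps - 1.5) < 0.015)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            VesselPathSpec("sinusoid", length_px=100, radius_px=3,
                           amplitude_px=120, wavelength_px=100)
        with pytest.raises(ValueError):
            VesselPathSpec("circular_arc", length_px=100, radius_px=5, arc_radius_px=4)
        with pytest.raises(ValueError):
            VesselPathSpec("helix", length_px=100, radius_px=3)
        sp = VesselPathSpec("straight", length_px=100, radius_px=2)
        with pytest.raises(ValueError):
            generate_vessel_path(sp, step_px=3.0)  # step > radius

    def test_amplitude_solver_inverts_mean_curvature(self):
        A = sinusoid_amplitude_for_curvature(0.01, wavelength=150, length=300)
        assert sinusoid_mean_curvature(A, 150, 300) == pytest.approx(0.01, rel=1e-6)


class TestRenderScene:
    def test_empty_path_list_gives_background_and_empty_truth(self):
        sc = render_scene([], image_size=(128, 128), seed=0)
        assert len(sc.truth_graph) == 0
        assert not sc.truth_mask.any()
        assert sc.image.pixels.min() > 0

    def test_centerline_is_darkest_along_cross_sections(self):
        sp = VesselPathSpec("straight", length_px=100, radius_px=3,
                            start_point=(64, 10), start_direction=(0, 1))
        sc = render_scene([sp], image_size=(128, 128), noise_sd=0.0, seed=0,
                          disk_center=(5, 5), disk_radius_px=1e-3)
        img = sc.image.pixels
        for col in (30, 50, 70):
            cross = img[54:75, col]
            assert np.argmin(cross) == 10  # row 64 is the axis

    def test_same_seed_is_bit_identical(self):
        sp = VesselPathSpec("straight", length_px=100, radius_px=3,
                            start_point=(64, 10), start_direction=(0, 1))
        kw = dict(image_size=(128, 128), noise_sd=0.04, illumination_gradient=0.2, seed=9)
        a = render_scene([sp], **kw)
        b = render_scene([sp], **kw)
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert np.array_equal(a.truth_mask, b.truth_mask)

    def test_truth_mask_equals_graph_rasterization(self, sparse_scene):
        again = rasterize_graph(sparse_scene.truth_graph, sparse_scene.truth_mask.shape)
        assert dice(sparse_scene.truth_mask, again) == 1.0

    def test_artery_shallower_than_vein(self, av_scene):
        img = av_scene.image.pixels
        mins = []
        for seg in av_scene.truth_graph.segments:
            r = int(round(seg.points[0][0]))
            mins.append((seg.av_label, img[r, 50:150].min()))
        artery = [v for l, v in mins if l == "artery"]
        vein = [v for l, v in mins if l == "vein"]
        assert min(artery) > max(vein)

    def test_clipped_path_warns_not_fails(self):
        sp = VesselPathSpec("straight", length_px=400, radius_px=3,
                            start_point=(64, 60), start_direction=(0, 1))
        with pytest.warns(UserWarning, match="clipped"):
            sc = render_scene([sp], image_size=(128, 128), seed=0)
        assert len(sc.truth_graph) == 1  # truncated but present


class TestCohort:
    def test_bookkeeping_counts_and_groups(self):
        spec = demo_cohort_spec(seed=0, n_patients=20)
        pats = simulate_cohort(spec, render=False)
        assert len(pats) == 20
        assert {p.group for p in pats} == set(GROUPS)
        assert len({p.patient_id for p in pats}) == 20

    def test_zero_between_patient_sd_gives_exact_targets(self):
        spec = demo_cohort_spec(seed=0, n_patients=8)
        spec.between_patient_sd = {c: 0.0 for c in REPORT_CLASSES}
        pats = simulate_cohort(spec, render=False)
        for p in pats:
            for cls in REPORT_CLASSES:
                assert p.true_tau[cls] == spec.group_tortuosity_means[p.group][cls]

    def test_cohort_draws_are_deterministic(self):
        spec = demo_cohort_spec(seed=5, n_patients=12)
        a = simulate_cohort(spec, render=False)
        b = simulate_cohort(spec, render=False)
        for x, y in zip(a, b):
            assert x.true_tau == y.true_tau

    def test_published_branch_artery_means_recovered_within_3_se(self):
        """Monte-Carlo: sample means converge to the configured group means.

        Branch-artery targets follow the published severity pattern
        (9.31, 9.48, 10.18, 13.96) x 1e-4 at n=200 per group.
        """
        means = {"nonDR": 9.31e-4, "V1": 9.48e-4, "V2": 10.18e-4, "V3": 13.96e-4}
        base = demo_cohort_spec(seed=11)
        spec = CohortSpec(
            group_sizes={g: 200 for g in GROUPS},
            group_tortuosity_means={
                g: {**base.group_tortuosity_means[g], "branch_artery": means[g]}
                for g in GROUPS
            },
            between_patient_sd={**base.between_patient_sd, "branch_artery": 5e-4},
            seed=11,
        )
        pats = simulate_cohort(spec, render=False)
        for g in GROUPS:
            vals = [p.true_tau["branch_artery"] for p in pats if p.group == g]
            se = 5e-4 / np.sqrt(len(vals))
            assert abs(np.mean(vals) - means[g]) < 3 * se + 0.06 * 5e-4  # + truncation slack

    def test_monotone_severity_trend_recovered_at_n50(self):
        spec = demo_cohort_spec(seed=3, n_patients=200)  # 50 per group
        pats = simulate_cohort(spec, render=False)
        med = {
            g: np.mean([p.true_tau["branch_artery"] for p in pats if p.group == g])
            for g in GROUPS
        }
        assert med["V1"] < med["V2"] < med["V3"]

    def test_default_spec_follows_published_group_sizes(self):
        spec = default_cohort_spec()
        assert spec.group_sizes == {"nonDR": 122, "V1": 200, "V2": 139, "V3": 34}

    def test_rendered_patient_matches_targets(self):
        spec = demo_cohort_spec(seed=2, n_patients=8, image_size=(256, 256))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pats = simulate_cohort(spec, render=True)
        p = pats[0]
        assert p.scene is not None
        by_class = {}
        for seg in p.scene.truth_graph.segments:
            kappa = p.scene.true_kappa[seg.seg_id]
            by_class.setdefault(seg.report_class, []).append(kappa)
        for cls, kappas in by_class.items():
            for k in kappas:  # every segment hits its class target exactly
                assert k == pytest.approx(p.true_tau[cls], rel=1e-6)
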