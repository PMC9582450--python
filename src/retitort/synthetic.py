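"""Synthetic fundus scenes and cohorts with ground-truth geometry.

The raw study images behind the cohort tables are not public, so every
downstream stage is exercised on generated scenes that emulate what a
confocal scanning laser ophthalmoscope green channel shows: a bright
circular optic disk from which a handful of large vessel trunks
radiate, thinner branch vessels splitting off the trunks, arteries
rendered with lower contrast and smaller caliber than veins, a slow
illumination gradient with corner vignetting, and additive sensor
noise.  The quantity under study — per-segment curvature — is
controllable and known in closed form, which is what makes the
tortuosity estimator testable.

Vessel centerlines come in three families:

* ``straight`` — zero curvature;
* ``circular_arc`` — constant curvature ``1/arc_radius_px``;
* ``sinusoid`` — a sine perturbation of a straight axis whose
  arc-length-weighted mean |curvature| has a closed-form integrand and
  is evaluated by dense quadrature.

Curvatures are in ``px^-1`` throughout; the physical pixel pitch of the
instrument is not anchored, so no micron conversion is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .core import GROUPS, REPORT_CLASSES, FundusImage, spawn_rng
from .graph import VesselGraph, VesselSegment, rasterize_graph

__all__ = [
    "VesselPathSpec",
    "SyntheticScene",
    "CohortSpec",
    "PatientScene",
    "generate_vessel_path",
    "render_scene",
    "simulate_cohort",
    "sinusoid_amplitude_for_curvature",
    "default_cohort_spec",
    "demo_cohort_spec",
]

_DENSE_STEP = 0.01  # px, for quadrature and arc-length resampling


@dataclass
class VesselPathSpec:
    """Geometric recipe for a single vessel centerline plus its tube."""

    path_family: str  # straight | circular_arc | sinusoid
    length_px: float
    radius_px: float
    start_point: tuple[float, float] = (0.0, 0.0)  # (row, col)
    start_direction: tuple[float, float] = (0.0, 1.0)  # unit (d_row, d_col)
    arc_radius_px: float | None = None
    amplitude_px: float | None = None
    wavelength_px: float | None = None
    turn: int = 1  # bending side for circular_arc / first sinusoid lobe
    vessel_class: str = "vein"  # artery | vein
    hierarchy: str = "main"  # main | branch

    def __post_init__(self) -> None:
        if self.path_family not in ("straight", "circular_arc", "sinusoid"):
            raise ValueError(f"unknown path family {self.path_family!r}")
        if self.length_px <= 0 or self.radius_px <= 0:
            raise ValueError("length_px and radius_px must be positive")
        d = np.asarray(self.start_direction, float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("start_direction must be nonzero")
        self.start_direction = tuple(d / n)
        if self.path_family == "circular_arc":
            if self.arc_radius_px is None or self.arc_radius_px <= self.radius_px:
                raise ValueError("circular_arc requires arc_radius_px > radius_px")
        if self.path_family == "sinusoid":
            if self.amplitude_px is None or self.wavelength_px is None:
                raise ValueError("sinusoid requires amplitude_px and wavelength_px")
            if self.amplitude_px < 0 or self.wavelength_px <= 0:
                raise ValueError("sinusoid parameters must be positive")
            if self.amplitude_px >= self.wavelength_px:
                raise ValueError(
                    "sinusoid amplitude must be smaller than its wavelength "
                    "(no self-overlap at rendered widths)"
                )


def _frame(spec: VesselPathSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p0 = np.asarray(spec.start_point, float)
    u = np.asarray(spec.start_direction, float)
    n = np.array([-u[1], u[0]]) * spec.turn  # left normal, flipped by turn
    return p0, u, n


def _dense_path(spec: VesselPathSpec) -> np.ndarray:
    """Dense (row, col) samples, approximately uniform in arc length."""
    p0, u, n = _frame(spec)
    if spec.path_family == "straight":
        t = np.arange(0.0, spec.length_px + _DENSE_STEP, _DENSE_STEP)
        return p0[None] + t[:, None] * u[None]
    if spec.path_family == "circular_arc":
        R = float(spec.arc_radius_px)
        s = np.arange(0.0, spec.length_px + _DENSE_STEP, _DENSE_STEP)
        phi = s / R
        # center at p0 + R*n; start tangent u
        return p0[None] + R * np.sin(phi)[:, None] * u[None] + R * (1 - np.cos(phi))[:, None] * n[None]
    # sinusoid: axis coordinate t, offset A sin(2 pi t / lam)
    A, lam = float(spec.amplitude_px), float(spec.wavelength_px)
    # oversample the axis; arc length >= axis length so extend a little
    t = np.arange(0.0, 1.2 * spec.length_px + _DENSE_STEP, _DENSE_STEP)
    y = A * np.sin(2 * np.pi * t / lam)
    pts = p0[None] + t[:, None] * u[None] + y[:, None] * n[None]
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    keep = s <= spec.length_px + _DENSE_STEP
    return pts[keep]


def sinusoid_mean_curvature(amplitude: float, wavelength: float, length: float) -> float:
    """Arc-length-weighted mean |kappa| of ``y = A sin(2 pi t / lam)``.

    Evaluated by dense quadrature of ``|y''| / (1 + y'^2)`` against
    ``sqrt(1 + y'^2) dt`` over the axis interval covered by a path of
    the given arc length.
    """
    if amplitude == 0:
        return 0.0
    A, lam = float(amplitude), float(wavelength)
    w = 2 * np.pi / lam
    # axis extent corresponding to the requested arc length
    t = np.arange(0.0, 1.2 * length, _DENSE_STEP)
    yp = A * w * np.cos(w * t)
    ds = np.sqrt(1 + yp**2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * _DENSE_STEP)])
    keep = s <= length
    t, yp, ds = t[keep], yp[keep], ds[keep]
    ypp = -A * w**2 * np.sin(w * t)
    kappa = np.abs(ypp) / (1 + yp**2) ** 1.5
    num = np.trapezoid(kappa * ds, t)
    den = np.trapezoid(ds, t)
    return float(num / den)


def sinusoid_amplitude_for_curvature(
    target_kappa: float, wavelength: float, length: float
) -> float:
    """Invert :func:`sinusoid_mean_curvature` for the amplitude.

    Mean curvature is monotone in amplitude over the physical range, so
    a bracketing root find is exact to the quadrature tolerance.
    """
    if target_kappa <= 0:
        return 0.0
    hi = wavelength / 3.0
    top = sinusoid_mean_curvature(hi, wavelength, length)
    if target_kappa >= top:
        raise ValueError(
            f"target curvature {target_kappa:g} not reachable at wavelength {wavelength:g}"
        )
    return brentq(
        lambda a: sinusoid_mean_curvature(a, wavelength, length) - target_kappa,
        0.0,
        hi,
        xtol=1e-10,
    )


def generate_vessel_path(
    spec: VesselPathSpec, step_px: float, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Sample a centerline at uniform arc step; return its analytic mean |kappa|.

    Consecutive points are ``step_px`` apart along the curve (to within
    the chord/arc discrepancy, < 1 %).  The returned curvature is the
    family's closed form: 0, ``1/arc_radius_px``, or the sinusoid
    quadrature.
    """
    if step_px <= 0:
        raise ValueError("step_px must be positive")
    if step_px > spec.radius_px:
        raise ValueError("step_px must not exceed radius_px")
    dense = _dense_path(spec)
    d = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    total = min(s[-1], spec.length_px)
    si = np.arange(0.0, total + 1e-9, step_px)
    rows = np.interp(si, s, dense[:, 0])
    cols = np.interp(si, s, dense[:, 1])
    points = np.stack([rows, cols], axis=1)

    if spec.path_family == "straight":
        kappa = 0.0
    elif spec.path_family == "circular_arc":
        kappa = 1.0 / float(spec.arc_radius_px)
    else:
        kappa = sinusoid_mean_curvature(
            spec.amplitude_px, spec.wavelength_px, spec.length_px
        )
    return points, kappa


# ---------------------------------------------------------------------------
# scene rendering


@dataclass
class SyntheticScene:
    image: FundusImage
    truth_graph: VesselGraph
    truth_mask: np.ndarray
    disk_center: tuple[float, float]
    disk_radius_px: float
    seed: int
    #: analytic mean curvature per truth segment id
    true_kappa: dict[int, float] = field(default_factory=dict)


DEFAULT_CONTRAST = {"artery": 0.35, "vein": 0.5}


def _background(shape, base, illumination_gradient):
    rows, cols = shape
    r, c = np.mgrid[0:rows, 0:cols].astype(float)
    ramp = (c / max(cols - 1, 1)) - 0.5
    cr, cc = (rows - 1) / 2, (cols - 1) / 2
    rad2 = ((r - cr) ** 2 + (c - cc) ** 2) / (cr**2 + cc**2)
    vignette = 1.0 - 0.4 * illumination_gradient * rad2
    return base * (1.0 + illumination_gradient * ramp) * vignette


def render_scene(
    paths: list[VesselPathSpec],
    image_size: tuple[int, int] = (768, 768),
    contrast: dict[str, float] | None = None,
    illumination_gradient: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    disk_center: tuple[float, float] | None = None,
    disk_radius_px: float = 60.0,
    base_intensity: float = 0.6,
    step_px: float | None = None,
    adjacency: dict[int, set[int]] | None = None,
) -> SyntheticScene:
    """Render vessel tubes into a fundus-like image with ground truth.

    Vessels attenuate the background multiplicatively with an inverted
    Gaussian cross-section, so they are always darker than the local
    background and the artery/vein contrast gap survives illumination
    gradients.  With ``noise_sd = 0`` and ``illumination_gradient = 0``
    the image is a deterministic function of the path list.
    """
    contrast = dict(DEFAULT_CONTRAST if contrast is None else contrast)
    for c in contrast.values():
        if not 0 < c <= 1:
            raise ValueError("contrast values must lie in (0, 1]")
    shape = tuple(int(v) for v in image_size)
    if disk_center is None:
        disk_center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)

    segments: list[VesselSegment] = []
    true_kappa: dict[int, float] = {}
    clipped = False
    for i, spec in enumerate(paths):
        step = step_px if step_px is not None else min(1.0, spec.radius_px)
        pts, kap = generate_vessel_path(spec, step_px=step, seed=seed)
        inside = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] <= shape[0] - 1)
            & (pts[:, 1] >= 0)
            & (pts[:, 1] <= shape[1] - 1)
        )
        if not inside.all():
            clipped = True
            # keep the leading in-bounds run so the polyline stays simple
            bad = np.flatnonzero(~inside)
            pts = pts[: bad[0]]
        if len(pts) < 5:
            clipped = True
            continue
        seg = VesselSegment(
            seg_id=i,
            points=pts,
            radius_px=np.full(len(pts), spec.radius_px),
            av_label=spec.vessel_class,
            hierarchy_label=spec.hierarchy,
        )
        segments.append(seg)
        true_kappa[i] = kap
    if clipped:
        warnings.warn("some paths extended outside the image and were clipped")

    adj = {s.seg_id: set() for s in segments}
    if adjacency:
        for k, v in adjacency.items():
            if k in adj:
                adj[k] |= {n for n in v if n in adj}
    graph = VesselGraph(
        segments=segments,
        adjacency=adj,
        disk_center=(float(disk_center[0]), float(disk_center[1])),
        disk_radius_px=float(disk_radius_px),
    )
    truth_mask = rasterize_graph(graph, shape)

    img = _background(shape, base_intensity, illumination_gradient)
    # bright optic disk: Gaussian blob
    r, c = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    d2 = (r - disk_center[0]) ** 2 + (c - disk_center[1]) ** 2
    img = img + 0.25 * base_intensity * np.exp(-d2 / (2 * (disk_radius_px / 1.5) ** 2))

    atten = np.ones(shape)
    for seg in segments:
        depth = contrast[seg.av_label]
        sigma = 0.6 * float(seg.radius_px[0])
        _stamp_tube_attenuation(atten, seg.points, sigma, depth)
    img = img * atten

    if noise_sd > 0:
        rng = spawn_rng(seed, "render-noise")
        img = img + rng.normal(0.0, noise_sd, shape)

    fimg = FundusImage(img, provenance=f"synthetic scene seed={seed}")
    return SyntheticScene(
        image=fimg,
        truth_graph=graph,
        truth_mask=truth_mask,
        disk_center=(float(disk_center[0]), float(disk_center[1])),
        disk_radius_px=float(disk_radius_px),
        seed=int(seed),
        true_kappa=true_kappa,
    )


def _stamp_tube_attenuation(atten, points, sigma, depth):
    """Multiply ``atten`` by the tube's inverted-Gaussian profile."""
    shape = atten.shape
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if len(points) > 1 and d.max() > 0.35:
        # densify for a smooth profile
        s = np.concatenate([[0.0], np.cumsum(d)])
        si = np.linspace(0, s[-1], max(int(s[-1] / 0.35) + 1, 2))
        points = np.stack(
            [np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])], axis=1
        )
    W = 3.5 * sigma
    lo = np.maximum(np.floor(points.min(axis=0) - W), 0).astype(int)
    hi = np.minimum(np.ceil(points.max(axis=0) + W + 1), shape).astype(int)
    if np.any(hi <= lo):
        return
    rr, cc = np.mgrid[lo[0]:hi[0], lo[1]:hi[1]]
    grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dist, _ = cKDTree(points).query(grid, k=1, distance_upper_bound=W)
    prof = np.zeros(len(grid))
    ok = np.isfinite(dist)
    prof[ok] = depth * np.exp(-(dist[ok] ** 2) / (2 * sigma**2))
    atten[lo[0]:hi[0], lo[1]:hi[1]] *= (1.0 - prof).reshape(rr.shape)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Study-level recipe: group sizes and per-class curvature targets.

    Group means/SDs are curvatures in px^-1 for each of the four vessel
    classes.  Their default pattern mirrors the published group
    structure (four severity groups, effects concentrated in branch
    arteries) at a spatial scale resolvable in a rendered image.
    """

    group_sizes: dict[str, int]
    group_tortuosity_means: dict[str, dict[str, float]]
    between_patient_sd: dict[str, float]
    seed: int = 0
    image_size: tuple[int, int] = (768, 768)
    disk_radius_px: float = 60.0
    trunk_radius_px: dict[str, float] = field(
        default_factory=lambda: {"vein": 5.0, "artery": 4.0}
    )
    branch_radius_ratio: float = 0.55
    n_trunks_range: tuple[int, int] = (4, 8)
    contrast: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONTRAST))
    illumination_gradient: float = 0.3
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        missing = [g for g in GROUPS if g not in self.group_sizes]
        if missing:
            raise ValueError(f"cohort spec missing groups: {missing}")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g} needs at least 2 patients")
        for g in GROUPS:
            means = self.group_tortuosity_means[g]
            for cls in REPORT_CLASSES:
                if means[cls] <= 0:
                    raise ValueError("curvature targets must be strictly positive")


@dataclass
class PatientScene:
    patient_id: str
    group: str
    #: per-class target mean curvature drawn for this patient (px^-1)
    true_tau: dict[str, float]
    scene: SyntheticScene | None = None


#: group-mean curvature pattern (px^-1) used by the default cohort; the
#: relative structure follows the published tables (monotone severity
#: trend concentrated in branch arteries) at one table unit = 1e-3 px^-1
TABLE_PATTERN_MEANS = {
    "nonDR": {"main_artery": 10.27e-3, "main_vein": 11.92e-3, "branch_artery": 9.31e-3, "branch_vein": 10.42e-3},
    "V1": {"main_artery": 10.50e-3, "main_vein": 12.17e-3, "branch_artery": 9.48e-3, "branch_vein": 10.35e-3},
    "V2": {"main_artery": 10.84e-3, "main_vein": 12.18e-3, "branch_artery": 10.18e-3, "branch_vein": 10.88e-3},
    "V3": {"main_artery": 11.28e-3, "main_vein": 12.28e-3, "branch_artery": 13.96e-3, "branch_vein": 12.31e-3},
}

TABLE_PATTERN_SDS = {"main_artery": 4.3e-3, "main_vein": 3.7e-3, "branch_artery": 5.3e-3, "branch_vein": 4.4e-3}

#: published group sizes: nonDR 122, mild 200, moderate 139, severe+PDR 34
TABLE_GROUP_SIZES = {"nonDR": 122, "V1": 200, "V2": 139, "V3": 34}


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(
        group_sizes=dict(TABLE_GROUP_SIZES),
        group_tortuosity_means={g: dict(m) for g, m in TABLE_PATTERN_MEANS.items()},
        between_patient_sd=dict(TABLE_PATTERN_SDS),
        seed=seed,
    )


def demo_cohort_spec(
    seed: int = 0,
    n_patients: int = 100,
    image_size: tuple[int, int] = (256, 256),
) -> CohortSpec:
    """Desk-scale cohort for end-to-end runs.

    Effects are injected only in branch-artery curvature (a strong,
    clearly detectable severity trend); the other three classes share
    one distribution across groups, so any group difference found there
    is spurious.  Group sizes are equal so the severe group is not
    starved at small n.
    """
    per = max(n_patients // 4, 2)
    sizes = {"nonDR": per, "V1": per, "V2": per, "V3": max(n_patients - 3 * per, 2)}
    null_means = {"main_artery": 10.0e-3, "main_vein": 12.0e-3, "branch_vein": 10.5e-3}
    ba = {"nonDR": 9.0e-3, "V1": 11.0e-3, "V2": 13.0e-3, "V3": 16.0e-3}
    means = {
        g: {**null_means, "branch_artery": ba[g]} for g in GROUPS
    }
    return CohortSpec(
        group_sizes=sizes,
        group_tortuosity_means=means,
        between_patient_sd={c: 2.0e-3 for c in REPORT_CLASSES},
        seed=seed,
        image_size=image_size,
        disk_radius_px=24.0,
        trunk_radius_px={"vein": 4.0, "artery": 3.2},
        branch_radius_ratio=0.45,
        n_trunks_range=(5, 7),
        noise_sd=0.03,
    )


def _truncated_normal(rng, mean, sd, lo=1e-5):
    if sd == 0:
        return float(mean)
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > lo:
            return float(v)
    return float(lo)


def _border_distance(p, u, shape, margin):
    """Distance from p along direction u to the margin-inset border."""
    t = np.inf
    for k in (0, 1):
        if u[k] > 1e-9:
            t = min(t, (shape[k] - 1 - margin - p[k]) / u[k])
        elif u[k] < -1e-9:
            t = min(t, (margin - p[k]) / u[k])
    return max(t, 0.0)


def _patient_paths(spec: CohortSpec, targets: dict[str, float], rng) -> list[VesselPathSpec]:
    """Lay out trunks and branches whose analytic curvature hits the targets."""
    shape = spec.image_size
    center = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    margin = 6.0
    n_trunks = int(rng.integers(spec.n_trunks_range[0], spec.n_trunks_range[1] + 1))
    phis = np.sort(rng.uniform(0, 2 * np.pi, n_trunks))
    # enforce minimal angular spacing so trunks don't merge at the disk
    phis = (phis[0] + np.linspace(0, 2 * np.pi, n_trunks, endpoint=False)
            + rng.uniform(-0.15, 0.15, n_trunks))
    paths: list[VesselPathSpec] = []
    for i, phi in enumerate(phis):
        vclass = "artery" if i % 2 == 0 else "vein"
        u = np.array([np.sin(phi), np.cos(phi)])
        start = center + (spec.disk_radius_px - 1.0) * u
        max_len = _border_distance(start, u, shape, margin)
        length = min(max_len, 0.46 * min(shape))
        if length < 12 * spec.trunk_radius_px[vclass]:
            continue
        radius = spec.trunk_radius_px[vclass]
        kappa = targets[f"main_{vclass}"]
        lam = length / 2.2
        try:
            A = sinusoid_amplitude_for_curvature(kappa, lam, length)
        except ValueError:
            A = lam / 3.5
        trunk = VesselPathSpec(
            path_family="sinusoid",
            length_px=length,
            radius_px=radius,
            start_point=tuple(start),
            start_direction=tuple(u),
            amplitude_px=A,
            wavelength_px=lam,
            turn=1 if rng.random() < 0.5 else -1,
            vessel_class=vclass,
            hierarchy="main",
        )
        paths.append(trunk)
        # one branch per trunk, splitting partway along
        t_frac = rng.uniform(0.35, 0.6)
        dense, _ = generate_vessel_path(trunk, step_px=min(1.0, radius))
        bi = int(t_frac * (len(dense) - 1))
        if bi < 2 or bi >= len(dense) - 2:
            continue
        bstart = dense[bi]
        tangent = dense[bi + 1] - dense[bi - 1]
        tangent = tangent / np.linalg.norm(tangent)
        ang = np.deg2rad(rng.uniform(35, 60)) * (1 if rng.random() < 0.5 else -1)
        ca, sa = np.cos(ang), np.sin(ang)
        bu = np.array([ca * tangent[0] + sa * tangent[1], -sa * tangent[0] + ca * tangent[1]])
        blen = min(_border_distance(bstart, bu, shape, margin), 0.30 * min(shape))
        bradius = spec.branch_radius_ratio * radius
        if blen < 10 * bradius:
            continue
        bkappa = targets[f"branch_{vclass}"]
        blam = max(blen / 1.6, 12 * bradius)
        try:
            bA = sinusoid_amplitude_for_curvature(bkappa, blam, blen)
        except ValueError:
            bA = blam / 3.5
        paths.append(
            VesselPathSpec(
                path_family="sinusoid",
                length_px=blen,
                radius_px=bradius,
                start_point=tuple(bstart),
                start_direction=tuple(bu),
                amplitude_px=bA,
                wavelength_px=blam,
                turn=1 if rng.random() < 0.5 else -1,
                vessel_class=vclass,
                hierarchy="branch",
            )
        )
    return paths


def simulate_cohort(spec: CohortSpec, render: bool = True) -> list[PatientScene]:
    """Draw a multi-group cohort of synthetic patients.

    Each patient's per-class mean curvature is drawn from that group's
    normal distribution (truncated at zero: curvature is positive) and
    the patient's vessels are constructed so that every segment of a
    class has exactly that analytic mean curvature.  With
    ``render=False`` only the ground-truth draws are produced, which is
    enough for cohort-level statistical checks and orders of magnitude
    faster.
    """
    patients: list[PatientScene] = []
    pid = 0
    for g in GROUPS:
        n = spec.group_sizes[g]
        means = spec.group_tortuosity_means[g]
        for j in range(n):
            rng = spawn_rng(spec.seed, "patient", g, j)
            targets = {
                cls: _truncated_normal(rng, means[cls], spec.between_patient_sd[cls])
                for cls in REPORT_CLASSES
            }
            scene = None
            if render:
                paths = _patient_paths(spec, targets, rng)
                scene = render_scene(
                    paths,
                    image_size=spec.image_size,
                    contrast=spec.contrast,
                    illumination_gradient=spec.illumination_gradient,
                    noise_sd=spec.noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    disk_radius_px=spec.disk_radius_px,
                )
            patients.append(
                PatientScene(
                    patient_id=f"P{pid:04d}", group=g, true_tau=targets, scene=scene
                )
            )
            pid += 1
    return patients
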