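"""Confidence-weighted curvature tortuosity via orientation scores.

The tortuosity of a vessel class is defined as the confidence-weighted
mean of local curvature along its centerlines:

    tau = sum_i c_i |kappa_i| / sum_i c_i

Curvature and confidence come from an orientation-score analysis.  The
2D image (or binary vessel mask) is lifted to a 3D function
``U(row, col, theta)`` by convolving with a bank of anisotropic,
orientation-selective cake wavelets — filters whose angular Fourier
support is a raised-cosine wedge and whose radial support is a
band-pass, so a straight dark-or-bright line responds maximally at its
own orientation.  At each centerline point the local vessel is then
modelled as a constant-curvature circular arc; lifted to the
orientation domain such an arc traces the exponential curve of the
roto-translation group through ``(point, theta)``.  Scanning a
curvature grid for the arc that maximizes the integral of ``U`` along
its lifted trace yields the local curvature estimate, and the maximal
integral itself (clamped at zero) is the confidence weight: well
resolved, high-contrast locations support their curvature estimate
strongly, while noisy or ambiguous locations contribute little to tau.

Tables report ``tau`` multiplied by 1e4 (curvature is in px^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import REPORT_CLASSES, REPORT_SCALE, FundusImage
from .graph import VesselGraph, VesselSegment

__all__ = [
    "OrientationScore",
    "CurvatureProfile",
    "TortuosityResult",
    "lift_orientation_score",
    "estimate_theta",
    "fit_local_curvature",
    "segment_curvature_profile",
    "graph_curvature_profiles",
    "overall_tortuosity",
    "oracle_curvature",
]

DEFAULT_N_THETA = 16
DEFAULT_FREQ_CENTER = 0.08  # cycles/px; tuned to vessel calibers of 2-10 px
DEFAULT_FREQ_BANDWIDTH = 2.0  # octaves
DEFAULT_WINDOW_PX = 31.0
DEFAULT_KAPPA_MAX = 0.1  # px^-1


@dataclass
class OrientationScore:
    """Lifted image: responses over position and unsigned orientation."""

    U: np.ndarray  # (rows, cols, n_theta)
    thetas: np.ndarray  # (n_theta,) in [0, pi)
    angular_aperture: float
    freq_center: float
    freq_bandwidth: float
    _Upad: np.ndarray | None = None  # cached periodic padding

    @property
    def n_theta(self) -> int:
        return self.U.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.U.shape[:2]


@dataclass
class CurvatureProfile:
    """Per-centerline-point curvature and confidence for one segment."""

    points: np.ndarray  # (n, 2) (row, col)
    kappa: np.ndarray  # (n,) unsigned, px^-1
    confidence: np.ndarray  # (n,) >= 0
    theta_star: np.ndarray  # (n,) in [0, pi)
    reliable: np.ndarray  # (n,) bool; False near borders
    av_label: str = "unknown"
    hierarchy_label: str = "unknown"

    @property
    def report_class(self) -> str:
        if "unknown" in (self.av_label, self.hierarchy_label):
            return "unknown"
        return f"{self.hierarchy_label}_{self.av_label}"


@dataclass
class TortuosityResult:
    """Confidence-weighted mean curvature for one vessel class."""

    vessel_class: str
    tau: float | None  # px^-1; None when the class has no confident point
    n_points: int = 0
    total_confidence: float = 0.0
    missing: bool = False

    @property
    def tau_scaled(self) -> float | None:
        """tau on the table scale (x 1e4)."""
        return None if self.tau is None else self.tau * REPORT_SCALE


# ---------------------------------------------------------------------------
# orientation lifting


def _cake_wavelet_bank(
    shape: tuple[int, int],
    thetas: np.ndarray,
    angular_aperture: float,
    freq_center: float,
    freq_bandwidth: float,
) -> np.ndarray:
    """Fourier-domain cake wavelets, one per orientation.

    Angular part: raised-cosine wedge of half-width ``angular_aperture``
    centered on the normal of each orientation (a line with tangent
    theta concentrates its spectrum perpendicular to theta), symmetric
    under point reflection so the spatial kernels are real and even.
    Radial part: log-Gabor band-pass, which is exactly zero at DC.
    """
    fr = np.fft.fftfreq(shape[0])[:, None]
    fc = np.fft.fftfreq(shape[1])[None, :]
    rho = np.hypot(fr, fc)
    phi = np.arctan2(fr, fc)  # angle of the frequency vector

    with np.errstate(divide="ignore"):
        lr = np.log(np.where(rho > 0, rho / freq_center, 1.0))
    slog = np.log(2.0) * freq_bandwidth / 2.0
    radial = np.exp(-(lr**2) / (2 * slog**2))
    radial[rho == 0] = 0.0  # zero-DC: constant images lift to ~0

    bank = np.empty((len(thetas),) + tuple(shape))
    for i, th in enumerate(thetas):
        # wedge centered at the line normal, folded onto [0, pi)
        delta = np.abs((phi - (th + np.pi / 2) + np.pi / 2) % np.pi - np.pi / 2)
        ang = np.where(
            delta < angular_aperture,
            np.cos(np.pi / 2 * delta / angular_aperture) ** 2,
            0.0,
        )
        bank[i] = ang * radial
    return bank


def lift_orientation_score(
    image: FundusImage | np.ndarray,
    n_theta: int = DEFAULT_N_THETA,
    angular_aperture: float | None = None,
    freq_center: float = DEFAULT_FREQ_CENTER,
    freq_bandwidth: float = DEFAULT_FREQ_BANDWIDTH,
    invert: bool = False,
) -> OrientationScore:
    """Lift a 2D image (or binary mask) to an orientation score.

    ``U[..., k]`` is the convolution of the input with the cake wavelet
    rotated to ``thetas[k]``; on a straight line the maximum over theta
    occurs at the line's own orientation (within one theta bin).  Set
    ``invert=True`` for dark-on-bright intensity images so vessels lift
    to positive responses.
    """
    pixels = image.pixels if isinstance(image, FundusImage) else np.asarray(image, float)
    if pixels.ndim != 2 or min(pixels.shape) < 64:
        raise ValueError("input must be a 2D image of at least 64x64")
    if n_theta < 8:
        raise ValueError("need n_theta >= 8")
    thetas = np.linspace(0.0, np.pi, n_theta, endpoint=False)
    if angular_aperture is None:
        angular_aperture = 2.0 * np.pi / n_theta
    if angular_aperture < np.pi / n_theta:
        raise ValueError(
            "angular aperture below pi/n_theta leaves gaps between wedges"
        )
    if invert:
        pixels = -pixels
    bank = _cake_wavelet_bank(
        pixels.shape, thetas, angular_aperture, freq_center, freq_bandwidth
    )
    F = np.fft.fft2(pixels)
    U = np.empty(pixels.shape + (n_theta,))
    for k in range(n_theta):
        U[..., k] = np.real(np.fft.ifft2(F * bank[k]))
    return OrientationScore(
        U=U,
        thetas=thetas,
        angular_aperture=float(angular_aperture),
        freq_center=float(freq_center),
        freq_bandwidth=float(freq_bandwidth),
    )


# ---------------------------------------------------------------------------
# local curvature by exponential-curve fitting


def _padded(score: OrientationScore) -> np.ndarray:
    """U with the first theta plane appended, for periodic interpolation."""
    if score._Upad is None:
        score._Upad = np.ascontiguousarray(
            np.concatenate([score.U, score.U[..., :1]], axis=2)
        )
    return score._Upad


def _arc_coordinates(points, theta, kappa, s):
    """Lifted constant-curvature arcs through (points, theta).

    ``points``: (N, 2); ``theta``: (N,); ``kappa``: (N, K); ``s``: (S,).
    Returns rows, cols, thetas arrays of shape (N, K, S).
    """
    th0 = theta[:, None, None]
    k = kappa[:, :, None]
    ss = s[None, None, :]
    th = th0 + k * ss
    small = np.abs(k) < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        # tangent (row, col) = (sin th, cos th); integrate over arc length
        drow = np.where(small, ss * np.sin(th0) + 0.5 * k * ss**2 * np.cos(th0),
                        (np.cos(th0) - np.cos(th)) / np.where(small, 1.0, k))
        dcol = np.where(small, ss * np.cos(th0) - 0.5 * k * ss**2 * np.sin(th0),
                        (np.sin(th) - np.sin(th0)) / np.where(small, 1.0, k))
    rows = points[:, 0][:, None, None] + drow
    cols = points[:, 1][:, None, None] + dcol
    return rows, cols, th


def _sample_integral(Upad, n_theta, rows, cols, thetas):
    """Mean of U along each candidate arc, by trilinear interpolation."""
    tcoord = (thetas % np.pi) / np.pi * n_theta
    coords = np.stack([rows.ravel(), cols.ravel(), tcoord.ravel()])
    vals = ndimage.map_coordinates(Upad, coords, order=1, mode="nearest")
    return vals.reshape(rows.shape).mean(axis=2)


def estimate_theta(score: OrientationScore, points: np.ndarray) -> np.ndarray:
    """Orientation at each point: argmax over theta, parabolic-refined."""
    points = np.atleast_2d(np.asarray(points, float))
    n = len(points)
    nt = score.n_theta
    coords = np.stack(
        [
            np.repeat(points[:, 0], nt),
            np.repeat(points[:, 1], nt),
            np.tile(np.arange(nt, dtype=float), n),
        ]
    )
    vals = ndimage.map_coordinates(
        _padded(score), coords, order=1, mode="nearest"
    ).reshape(n, nt)
    k = np.argmax(vals, axis=1)
    left = vals[np.arange(n), (k - 1) % nt]
    mid = vals[np.arange(n), k]
    right = vals[np.arange(n), (k + 1) % nt]
    denom = left - 2 * mid + right
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (left - right) / np.where(denom == 0, 1, denom), 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    return ((k + shift) * np.pi / nt) % np.pi


def snap_to_ridge(
    score: OrientationScore,
    points: np.ndarray,
    theta: np.ndarray,
    max_offset_px: float = 2.0,
    step_px: float = 0.25,
) -> np.ndarray:
    """Move points onto the response ridge along the vessel normal.

    The lifted response of a curved vessel peaks slightly inside the
    geometric centerline (the elongated wavelets integrate a bending
    curve), so curvature fitted through off-ridge points overshoots.
    Sampling ``U(., theta)`` along the normal and re-centering each
    point at the parabolic peak removes this first-order displacement.
    """
    points = np.atleast_2d(np.asarray(points, float))
    theta = np.broadcast_to(np.asarray(theta, float), (len(points),))
    offs = np.arange(-max_offset_px, max_offset_px + step_px / 2, step_px)
    normal = np.stack([np.cos(theta), -np.sin(theta)], axis=1)  # (n, 2)
    pos = points[:, None, :] + offs[None, :, None] * normal[:, None, :]
    nt = score.n_theta
    tcoord = np.broadcast_to(((theta % np.pi) / np.pi * nt)[:, None], pos.shape[:2])
    coords = np.stack([pos[..., 0].ravel(), pos[..., 1].ravel(), tcoord.ravel()])
    vals = ndimage.map_coordinates(_padded(score), coords, order=1, mode="nearest")
    vals = vals.reshape(len(points), len(offs))
    best = np.argmax(vals, axis=1)
    idx = np.arange(len(points))
    shift = np.zeros(len(points))
    interior = (best > 0) & (best < len(offs) - 1)
    l = vals[idx, np.maximum(best - 1, 0)]
    m = vals[idx, best]
    r = vals[idx, np.minimum(best + 1, len(offs) - 1)]
    denom = l - 2 * m + r
    ok = interior & (np.abs(denom) > 1e-15)
    shift[ok] = np.clip(0.5 * (l[ok] - r[ok]) / denom[ok], -0.5, 0.5)
    snapped = points + (offs[best] + shift * step_px)[:, None] * normal
    return snapped


def fit_local_curvature(
    score: OrientationScore,
    points: np.ndarray,
    theta_star: np.ndarray | float,
    window_px: float = DEFAULT_WINDOW_PX,
    kappa_max: float = DEFAULT_KAPPA_MAX,
    n_coarse: int = 41,
    n_fine: int = 17,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best-fitting constant-curvature lifted curve at each point.

    For every candidate curvature on a coarse grid over
    ``[-kappa_max, kappa_max]`` the mean of ``U`` along the lifted arc
    of length ``window_px`` through ``(point, theta_star)`` is
    evaluated; a second, fine grid around each point's best candidate
    plus a final parabolic step give sub-grid resolution.  Returns
    ``(kappa, confidence, reliable)`` — curvature is signed here;
    callers take ``|kappa|`` for tortuosity.  Points whose window
    extends outside the image are flagged unreliable.
    """
    points = np.atleast_2d(np.asarray(points, float))
    n = len(points)
    theta = np.broadcast_to(np.asarray(theta_star, float), (n,)).copy()
    half = window_px / 2.0
    n_s = max(9, int(round(window_px)) | 1)
    s = np.linspace(-half, half, n_s)
    Upad = _padded(score)
    nt = score.n_theta

    margin = half
    reliable = (
        (points[:, 0] >= margin)
        & (points[:, 0] <= score.shape[0] - 1 - margin)
        & (points[:, 1] >= margin)
        & (points[:, 1] <= score.shape[1] - 1 - margin)
    )

    coarse = np.linspace(-kappa_max, kappa_max, n_coarse)
    kgrid = np.broadcast_to(coarse, (n, n_coarse))
    rows, cols, ths = _arc_coordinates(points, theta, kgrid, s)
    integ = _sample_integral(Upad, nt, rows, cols, ths)
    best = np.argmax(integ, axis=1)
    k_best = coarse[best]

    step = coarse[1] - coarse[0]
    offsets = np.linspace(-step, step, n_fine)
    kfine = k_best[:, None] + offsets[None, :]
    np.clip(kfine, -kappa_max, kappa_max, out=kfine)
    rows, cols, ths = _arc_coordinates(points, theta, kfine, s)
    integ_f = _sample_integral(Upad, nt, rows, cols, ths)
    bf = np.argmax(integ_f, axis=1)
    idx = np.arange(n)
    kappa = kfine[idx, bf]
    conf = integ_f[idx, bf]

    # parabolic sub-step around the fine optimum (interior maxima only)
    interior = (bf > 0) & (bf < n_fine - 1)
    if np.any(interior):
        l = integ_f[idx, np.maximum(bf - 1, 0)]
        r = integ_f[idx, np.minimum(bf + 1, n_fine - 1)]
        denom = l - 2 * conf + r
        ok = interior & (np.abs(denom) > 1e-15)
        fstep = offsets[1] - offsets[0]
        shift = np.zeros(n)
        shift[ok] = np.clip(0.5 * (l[ok] - r[ok]) / denom[ok], -0.5, 0.5)
        kappa = np.clip(kappa + shift * fstep, -kappa_max, kappa_max)

    conf = np.maximum(conf, 0.0)
    conf[~reliable] = 0.0
    return kappa, conf, reliable


def segment_curvature_profile(
    score: OrientationScore,
    segment: VesselSegment,
    window_px: float | str = DEFAULT_WINDOW_PX,
    stride: int = 1,
    theta_source: str = "score",
    snap: bool = True,
    trim_ends: bool = True,
    **fit_kwargs,
) -> CurvatureProfile:
    """Curvature profile along one centerline segment.

    ``theta_source`` picks the local orientation handed to the fit:
    ``"score"`` uses the orientation-score argmax (self-contained, as in
    the lifting construction), ``"tangent"`` uses the centerline's own
    finite-difference tangent.  With ``snap`` the points are first
    re-centered on the response ridge (see :func:`snap_to_ridge`).
    With ``trim_ends`` points within half a window of either segment
    end are flagged unreliable (their fit window has one-sided vessel
    support, which biases curvature low); segments shorter than 1.5
    windows are kept whole since trimming would discard them entirely.

    ``window_px="auto"`` scales the window with the segment's mean
    radius (12.4 radii, clipped to [21, 63] px).  Curvature selectivity
    at a fixed window degrades as vessels get wider, so a
    caliber-tracking window is what keeps tau covariant under spatial
    rescaling of a whole scene.
    """
    if window_px == "auto":
        window_px = float(np.clip(12.4 * segment.mean_radius, 21.0, 63.0))
    pts = segment.points[::max(int(stride), 1)]
    if theta_source == "score":
        theta = estimate_theta(score, pts)
    elif theta_source == "tangent":
        full = segment.points
        grad = np.gradient(full, axis=0)
        ang = np.arctan2(grad[:, 0], grad[:, 1]) % np.pi
        theta = ang[::max(int(stride), 1)]
    else:
        raise ValueError("theta_source must be 'score' or 'tangent'")
    if snap:
        pts = snap_to_ridge(score, pts, theta)
        theta = estimate_theta(score, pts) if theta_source == "score" else theta
    kappa, conf, reliable = fit_local_curvature(
        score, pts, theta, window_px=window_px, **fit_kwargs
    )
    if trim_ends and len(pts) > 1:
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(d)])
        if s[-1] > 1.5 * window_px:
            interior = (s > window_px / 2) & (s < s[-1] - window_px / 2)
            reliable = reliable & interior
            conf = np.where(reliable, conf, 0.0)
    return CurvatureProfile(
        points=pts,
        kappa=np.abs(kappa),
        confidence=conf,
        theta_star=theta,
        reliable=reliable,
        av_label=segment.av_label,
        hierarchy_label=segment.hierarchy_label,
    )


def graph_curvature_profiles(
    score: OrientationScore,
    graph: VesselGraph,
    window_px: float = DEFAULT_WINDOW_PX,
    stride: int = 1,
    **kwargs,
) -> list[CurvatureProfile]:
    """Profiles for every labelled segment of a graph."""
    return [
        segment_curvature_profile(score, seg, window_px=window_px, stride=stride, **kwargs)
        for seg in graph.segments
        if seg.n_points >= 5
    ]


def overall_tortuosity(
    profiles: list[CurvatureProfile],
    classes: tuple[str, ...] = REPORT_CLASSES,
) -> dict[str, TortuosityResult]:
    """Pool profiles per vessel class into confidence-weighted tau.

    Pooling is over all points of a class across vessels and the
    weighted mean is taken once (not per vessel first).  A class with
    no point of positive confidence is flagged missing rather than
    zero-filled.
    """
    out: dict[str, TortuosityResult] = {}
    for cls in classes:
        ks, cs = [], []
        for p in profiles:
            if p.report_class == cls:
                ks.append(np.abs(p.kappa))
                cs.append(p.confidence)
        if not ks:
            out[cls] = TortuosityResult(cls, None, 0, 0.0, missing=True)
            continue
        kappa = np.concatenate(ks)
        conf = np.concatenate(cs)
        total = float(conf.sum())
        if total <= 0:
            out[cls] = TortuosityResult(cls, None, len(kappa), 0.0, missing=True)
            continue
        tau = float(np.sum(conf * kappa) / total)
        out[cls] = TortuosityResult(cls, tau, len(kappa), total, missing=False)
    return out


# ---------------------------------------------------------------------------
# independent geometric oracle


def oracle_curvature(points: np.ndarray, smoothing: float = 0.0) -> np.ndarray:
    """Spline-based curvature of a polyline, independent of any lifting.

    Fits smoothing splines to row(s) and col(s) against arc length and
    evaluates |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2).  Used as the
    testing oracle for the orientation-score estimator.
    """
    from scipy.interpolate import splev, splrep

    points = np.asarray(points, float)
    if len(points) < 7:
        raise ValueError("need at least 7 points")
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(d == 0):
        raise ValueError("repeated points are degenerate for arc length")
    s = np.concatenate([[0.0], np.cumsum(d)])
    tx = splrep(s, points[:, 1], s=smoothing * len(points))
    ty = splrep(s, points[:, 0], s=smoothing * len(points))
    xp, yp = splev(s, tx, der=1), splev(s, ty, der=1)
    xpp, ypp = splev(s, tx, der=2), splev(s, ty, der=2)
    return np.abs(xp * ypp - yp * xpp) / (xp**2 + yp**2) ** 1.5
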