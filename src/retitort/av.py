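"""Artery/vein discrimination from intensity features.

On green-channel SLO images veins are darker and wider than arteries,
so simple intensity statistics around each vessel separate the two
classes well.  Per segment, ten features are computed: the mean,
standard deviation, median, minimum and maximum of the intensities (a)
inside circular regions centered on the centerline points and (b)
sampled along the centerline itself.  A logistic regression on the
standardized features yields a per-segment label and probability; the
segment's label is propagated to all its points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import FundusImage
from .graph import VesselGraph, VesselSegment

FEATURE_NAMES = (
    "circ_mean", "circ_sd", "circ_median", "circ_min", "circ_max",
    "line_mean", "line_sd", "line_median", "line_min", "line_max",
)

#: class encoding for the logistic model
POSITIVE_CLASS = "artery"


@dataclass
class SegmentFeatures:
    """The ten intensity statistics for one vessel segment."""

    circ_mean: float
    circ_sd: float
    circ_median: float
    circ_min: float
    circ_max: float
    line_mean: float
    line_sd: float
    line_median: float
    line_min: float
    line_max: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


@dataclass
class AVModel:
    """Standardization + logistic weights; JSON-serializable."""

    weights: np.ndarray  # (10,)
    intercept: float
    feat_mean: np.ndarray  # (10,)
    feat_scale: np.ndarray  # (10,)
    n_train: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.feat_mean = np.asarray(self.feat_mean, float)
        self.feat_scale = np.asarray(self.feat_scale, float)
        if not (np.all(np.isfinite(self.weights)) and np.isfinite(self.intercept)):
            raise ValueError("model weights must be finite")
        if np.any(self.feat_scale <= 0):
            raise ValueError("feature scales must be positive (standardization invertible)")

    def decision(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(X) - self.feat_mean) / self.feat_scale
        return Z @ self.weights + self.intercept

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("weights", "feat_mean", "feat_scale"):
            d[k] = list(map(float, d[k]))
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AVModel":
        return cls(**json.loads(text))


def _stats(values: np.ndarray) -> tuple[float, float, float, float, float]:
    return (
        float(np.mean(values)),
        float(np.std(values)),
        float(np.median(values)),
        float(np.min(values)),
        float(np.max(values)),
    )


def extract_features(
    image: FundusImage,
    segment: VesselSegment,
    circle_radius_factor: float = 1.5,
) -> SegmentFeatures:
    """Intensity statistics inside circular regions and along the centerline.

    The circular regions have radius ``circle_radius_factor`` times the
    local vessel radius, so they cover the vessel plus its immediate
    surround; their union over all centerline points forms the sampled
    region.
    """
    if circle_radius_factor <= 0:
        raise ValueError("circle_radius_factor must be positive")
    pts = segment.points
    shape = image.shape
    if (
        pts[:, 0].min() < 0 or pts[:, 0].max() > shape[0] - 1
        or pts[:, 1].min() < 0 or pts[:, 1].max() > shape[1] - 1
    ):
        raise ValueError("segment extends outside the image")

    line_vals = ndimage.map_coordinates(image.pixels, pts.T, order=1, mode="nearest")

    radii = np.maximum(segment.radius_px, 0.5) * circle_radius_factor
    rmax = float(radii.max())
    lo = np.maximum(np.floor(pts.min(axis=0) - rmax), 0).astype(int)
    hi = np.minimum(np.ceil(pts.max(axis=0) + rmax + 1), shape).astype(int)
    rr, cc = np.mgrid[lo[0]:hi[0], lo[1]:hi[1]]
    grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dist, idx = cKDTree(pts).query(grid, k=1, distance_upper_bound=rmax + 1)
    ok = np.isfinite(dist)
    inside = np.zeros(len(grid), bool)
    inside[ok] = dist[ok] <= radii[np.clip(idx[ok], 0, len(radii) - 1)]
    circ_vals = image.pixels[lo[0]:hi[0], lo[1]:hi[1]].ravel()[inside]
    if circ_vals.size == 0:  # degenerate tiny segment
        circ_vals = line_vals

    c = _stats(circ_vals)
    l = _stats(line_vals)
    return SegmentFeatures(*c, *l)


def graph_features(
    image: FundusImage, graph: VesselGraph, circle_radius_factor: float = 1.5
) -> np.ndarray:
    """Feature matrix (n_segments, 10) in graph segment order."""
    return np.array(
        [extract_features(image, s, circle_radius_factor).as_array() for s in graph.segments]
    )


def train_av(
    features: np.ndarray,
    labels: list[str],
    seed: int = 0,
    ridge: float = 1e-6,
) -> AVModel:
    """Maximum-likelihood logistic fit on standardized features.

    A tiny L2 ridge keeps the fit defined on separable data (the usual
    case for clean synthetic cohorts).  Deterministic given the data
    ordering and seed.
    """
    from sklearn.linear_model import LogisticRegression

    X = np.atleast_2d(np.asarray(features, float))
    y = np.array([1 if l == POSITIVE_CLASS else 0 for l in labels])
    if len(X) < 10:
        raise ValueError("need at least 10 labelled segments")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    clf = LogisticRegression(
        C=1.0 / ridge, solver="lbfgs", max_iter=2000, random_state=int(seed) & 0x7FFFFFFF
    )
    clf.fit(Z, y)
    return AVModel(
        weights=clf.coef_[0],
        intercept=float(clf.intercept_[0]),
        feat_mean=mean,
        feat_scale=scale,
        n_train=len(X),
        seed=int(seed),
    )


def classify_av(model: AVModel, features: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Per-segment labels and artery probabilities."""
    X = np.atleast_2d(np.asarray(features, float))
    if X.shape[1] != len(model.weights):
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension {len(model.weights)}"
        )
    p = 1.0 / (1.0 + np.exp(-model.decision(X)))
    labels = [POSITIVE_CLASS if pi >= 0.5 else "vein" for pi in p]
    return labels, p


def apply_av_labels(graph: VesselGraph, model: AVModel, image: FundusImage,
                    circle_radius_factor: float = 1.5) -> VesselGraph:
    """Classify every segment of a graph in place."""
    if not graph.segments:
        return graph
    X = graph_features(image, graph, circle_radius_factor)
    labels, _ = classify_av(model, X)
    for seg, lab in zip(graph.segments, labels):
        seg.av_label = lab
    return graph
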