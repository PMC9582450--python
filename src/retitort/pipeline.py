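"""End-to-end orchestration: scene -> segmentation -> graph -> A/V ->
tortuosity -> cohort tables.

The stage order follows the analysis design: local normalization
first, then vessel enhancement and thresholding, centerline graph
extraction with the optic-disk main/branch split, artery/vein
classification, orientation-score curvature, and finally the cohort
statistics.  A single global seed drives every stage through derived
substreams, so identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import __version__
from .av import AVModel, classify_av, graph_features, train_av
from .core import REPORT_CLASSES, dice
from .graph import VesselGraph, extract_centerlines, split_main_branch
from .segmentation import (
    DEFAULT_N_ORIENTATIONS,
    DEFAULT_SCALES,
    enhance_vessels,
    local_normalize,
    segment_vessels,
)
from .stats import CohortTable, PatientRecord, summarize_cohort
from .synthetic import CohortSpec, PatientScene, SyntheticScene, simulate_cohort
from .tortuosity import (
    DEFAULT_N_THETA,
    DEFAULT_WINDOW_PX,
    graph_curvature_profiles,
    lift_orientation_score,
    overall_tortuosity,
)


@dataclass
class PipelineParams:
    """Tunable parameters of the analysis stages (all in pixels)."""

    norm_window_px: int = 65
    scales_px: tuple[float, ...] = DEFAULT_SCALES
    n_orientations: int = DEFAULT_N_ORIENTATIONS
    min_length_px: float = 10.0
    caliber_quantile: float = 0.8
    circle_radius_factor: float = 1.5
    n_theta: int = DEFAULT_N_THETA
    window_px: float = DEFAULT_WINDOW_PX
    stride: int = 2
    n_train_patients: int = 6  # scenes whose truth labels train the A/V model

    def validate(self, image_size: tuple[int, int] | None = None) -> None:
        if self.norm_window_px % 2 == 0 or self.norm_window_px < 3:
            raise ValueError("params.norm_window_px must be an odd integer >= 3")
        if not self.scales_px or any(s <= 0.5 for s in self.scales_px):
            raise ValueError("params.scales_px must all exceed 0.5")
        if self.n_orientations < 4:
            raise ValueError("params.n_orientations must be >= 4")
        if self.n_theta < 8:
            raise ValueError("params.n_theta must be >= 8")
        if not 0 < self.caliber_quantile < 1:
            raise ValueError("params.caliber_quantile must be in (0, 1)")
        if self.window_px < 5:
            raise ValueError("params.window_px must be >= 5")
        if image_size is not None:
            if self.norm_window_px >= min(image_size):
                raise ValueError("params.norm_window_px must be smaller than the image")
            if max(self.scales_px) * 6 > min(image_size):
                raise ValueError("params.scales_px: largest scale does not fit the image")


@dataclass
class PatientAnalysis:
    record: PatientRecord
    dice: float
    hierarchy_accuracy: float
    av_accuracy: float
    n_segments: int


def transfer_truth_labels(
    graph: VesselGraph, truth: VesselGraph, max_dist_px: float = 4.0
) -> tuple[list[str], list[str]]:
    """Majority-vote truth labels for each extracted segment.

    Matches every centerline point of an extracted segment to the
    nearest ground-truth centerline point (within ``max_dist_px``) and
    votes.  Used to build training labels and accuracy metrics on
    synthetic scenes; returns (av_labels, hierarchy_labels) with
    ``"unknown"`` for unmatched segments.
    """
    if not truth.segments or not graph.segments:
        return (["unknown"] * len(graph.segments),) * 2
    tpts = np.concatenate([s.points for s in truth.segments])
    tav, thier = [], []
    for s in truth.segments:
        tav += [s.av_label] * s.n_points
        thier += [s.hierarchy_label] * s.n_points
    tav, thier = np.array(tav), np.array(thier)
    tree = cKDTree(tpts)
    av_out, hier_out = [], []
    for seg in graph.segments:
        d, idx = tree.query(seg.points, k=1, distance_upper_bound=max_dist_px)
        ok = np.isfinite(d)
        if not ok.any():
            av_out.append("unknown")
            hier_out.append("unknown")
            continue
        idx = idx[ok]
        av_vals, av_counts = np.unique(tav[idx], return_counts=True)
        h_vals, h_counts = np.unique(thier[idx], return_counts=True)
        av_out.append(str(av_vals[np.argmax(av_counts)]))
        hier_out.append(str(h_vals[np.argmax(h_counts)]))
    return av_out, hier_out


def extract_graph_from_scene(
    scene: SyntheticScene, params: PipelineParams
) -> tuple[VesselGraph, np.ndarray]:
    """Segmentation + centerline + main/branch stages for one scene."""
    norm = local_normalize(scene.image, params.norm_window_px)
    vmap = enhance_vessels(norm, params.scales_px, params.n_orientations)
    mask = segment_vessels(vmap)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = extract_centerlines(mask, params.min_length_px)
        if graph.segments:
            split_main_branch(
                graph, scene.disk_center, scene.disk_radius_px, params.caliber_quantile
            )
    return graph, mask


def analyze_scene(
    scene: SyntheticScene,
    params: PipelineParams,
    av_model: AVModel | None,
    patient_id: str = "P0000",
    group: str = "nonDR",
) -> PatientAnalysis:
    """Full single-patient analysis; accuracy metrics versus scene truth."""
    graph, mask = extract_graph_from_scene(scene, params)
    truth_av, truth_hier = transfer_truth_labels(graph, scene.truth_graph)

    av_acc = float("nan")
    if graph.segments and av_model is not None:
        X = graph_features(scene.image, graph, params.circle_radius_factor)
        labels, _ = classify_av(av_model, X)
        for seg, lab in zip(graph.segments, labels):
            seg.av_label = lab
        known = [
            (lab, t)
            for lab, t in zip(labels, truth_av)
            if t != "unknown"
        ]
        if known:
            av_acc = float(np.mean([lab == t for lab, t in known]))

    lengths = np.array([s.arc_length() for s in graph.segments])
    hier_ok = np.array(
        [
            s.hierarchy_label == t
            for s, t in zip(graph.segments, truth_hier)
        ]
    ) if graph.segments else np.array([])
    matched = np.array([t != "unknown" for t in truth_hier]) if graph.segments else np.array([])
    hier_acc = (
        float(lengths[matched & hier_ok].sum() / lengths[matched].sum())
        if matched.any()
        else float("nan")
    )

    tau: dict[str, float | None] = {cls: None for cls in REPORT_CLASSES}
    if graph.segments:
        norm = local_normalize(scene.image, params.norm_window_px)
        score = lift_orientation_score(norm, n_theta=params.n_theta, invert=True)
        profiles = graph_curvature_profiles(
            score, graph, window_px=params.window_px, stride=params.stride
        )
        results = overall_tortuosity(profiles)
        tau = {
            cls: (None if r.missing else r.tau_scaled) for cls, r in results.items()
        }
    return PatientAnalysis(
        record=PatientRecord(patient_id, group, tau),
        dice=dice(mask, scene.truth_mask),
        hierarchy_accuracy=hier_acc,
        av_accuracy=av_acc,
        n_segments=len(graph.segments),
    )


def train_av_from_patients(
    patients: list[PatientScene], params: PipelineParams, seed: int = 0
) -> AVModel:
    """Fit the A/V model on extracted segments with truth-derived labels.

    Stands in for the expert-labelled training data of the original
    analysis, which is not available; labels come from the synthetic
    ground truth via nearest-centerline matching.
    """
    feats, labels = [], []
    step = max(len(patients) // max(params.n_train_patients, 1), 1)
    for pat in patients[::step][: params.n_train_patients]:
        graph, _ = extract_graph_from_scene(pat.scene, params)
        if not graph.segments:
            continue
        av, _ = transfer_truth_labels(graph, pat.scene.truth_graph)
        X = graph_features(pat.scene.image, graph, params.circle_radius_factor)
        for x, lab in zip(X, av):
            if lab in ("artery", "vein"):
                feats.append(x)
                labels.append(lab)
    return train_av(np.array(feats), labels, seed=seed)


def run_cohort_analysis(
    spec: CohortSpec, params: PipelineParams | None = None
) -> tuple[list[PatientAnalysis], CohortTable]:
    """Simulate a cohort and push every patient through the pipeline."""
    params = params or PipelineParams()
    params.validate(spec.image_size)
    patients = simulate_cohort(spec, render=True)
    model = train_av_from_patients(patients, params, seed=spec.seed)
    analyses = [
        analyze_scene(p.scene, params, model, p.patient_id, p.group) for p in patients
    ]
    table = summarize_cohort([a.record for a in analyses])
    return analyses, table


# --------------------------------------------------------------------------- file-level run


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the full pipeline from a config mapping; return the manifest.

    The config mirrors :class:`CohortSpec` (under ``cohort``) and
    :class:`PipelineParams` (under ``params``); every parameter is
    validated before any stage runs.  Outputs: ``patients.csv``, the
    two cohort tables, the A/V model, and ``manifest.json``.
    """
    from .io import patients_to_csv, save_cohort_table
    from .synthetic import demo_cohort_spec

    out_dir = Path(out_dir)
    seed = int(config.get("seed", 0))
    cohort_cfg = dict(config.get("cohort", {}))
    params_cfg = dict(config.get("params", {}))

    unknown = set(params_cfg) - set(PipelineParams.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown params fields: {sorted(unknown)}")
    params = PipelineParams(**params_cfg)
    if "scales_px" in params_cfg:
        params.scales_px = tuple(params_cfg["scales_px"])

    spec_fields = set(CohortSpec.__dataclass_fields__)
    if {"group_sizes", "group_tortuosity_means", "between_patient_sd"} <= set(cohort_cfg):
        unknown = set(cohort_cfg) - spec_fields
        if unknown:
            raise ValueError(f"unknown cohort fields: {sorted(unknown)}")
        if "image_size" in cohort_cfg:
            cohort_cfg["image_size"] = tuple(cohort_cfg["image_size"])
        spec = CohortSpec(seed=seed, **{k: v for k, v in cohort_cfg.items() if k != "seed"})
    else:
        allowed = {"n_patients", "image_size"}
        unknown = set(cohort_cfg) - allowed
        if unknown:
            raise ValueError(
                f"cohort config must either be a full spec or use {sorted(allowed)}; "
                f"got unknown fields {sorted(unknown)}"
            )
        spec = demo_cohort_spec(
            seed=seed,
            n_patients=int(cohort_cfg.get("n_patients", 20)),
            image_size=tuple(cohort_cfg.get("image_size", (256, 256))),
        )
    params.validate(spec.image_size)

    t0 = time.time()
    out_dir.mkdir(parents=True, exist_ok=True)
    analyses, table = run_cohort_analysis(spec, params)
    patients_csv = out_dir / "patients.csv"
    patients_to_csv(patients_csv, [a.record for a in analyses])
    table_paths = save_cohort_table(out_dir, table)

    qc = {
        "mean_dice": float(np.nanmean([a.dice for a in analyses])),
        "mean_hierarchy_accuracy": float(np.nanmean([a.hierarchy_accuracy for a in analyses])),
        "mean_av_accuracy": float(np.nanmean([a.av_accuracy for a in analyses])),
        "n_patients": len(analyses),
    }
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "outputs": {
            "patients_csv": str(patients_csv),
            **{k: str(v) for k, v in table_paths.items()},
        },
        "qc": qc,
        "runtime_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
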