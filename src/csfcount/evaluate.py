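"""End-to-end evaluation harness: dilution series, truth-based accuracy,
and the full image-pair counting pipeline.

The harness exercises the complete chain — scene synthesis, dual-modality
rendering, circle detection, enumeration — under fully seeded conditions,
reproducing the structure of the platform's validation experiments (serial
dilution with replicate chambers; agreement of automated counts with an
independent reference) on synthetic scenes where the reference is the
generator's ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from . import __version__
from .config import PipelineConfig
from .counting import AreaCount, concentrations, count_area
from .errors import InputError, ValidationError
from .hough import find_circles, match_detections
from .image import load_frame
from .simulate import (
    render_brightfield,
    render_fluorescence,
    sample_scene,
    settled,
)

logger = logging.getLogger(__name__)

DEFAULT_DILUTION_SERIES = (5.2, 16.0, 65.0, 260.0, 1040.0)
MATCH_TOL_UM = 3.0


@dataclass(frozen=True)
class DilutionPoint:
    expected_conc: float
    measured_mean: float
    measured_sd: float
    cv: float


@dataclass(frozen=True)
class DilutionSeriesResult:
    """Linearity of measured vs expected concentration for one cell class."""

    points: tuple[DilutionPoint, ...]
    slope: float
    intercept: float
    r_squared: float
    cell_class: str


def _sub_seed(seed: int, *parts: int) -> int:
    """Deterministic 31-bit sub-seed from a base seed and index path."""
    h = hashlib.sha256(np.array([seed, *parts], dtype=np.int64).tobytes()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _measure_chamber(
    c_rbc: float, c_wbc: float, config: PipelineConfig, seed: int
) -> tuple[list[AreaCount], list, list]:
    """Simulate and count one chamber (n_areas settled frame pairs)."""
    sim = config.simulator
    per_area = []
    bf_all, truth_all = [], []
    for area in range(config.chamber.n_areas):
        scene = settled(
            sample_scene(
                c_rbc, c_wbc, config.optics, config.chamber,
                debris_rate=sim.debris_rate, clump_rate=sim.clump_rate,
                seed=_sub_seed(seed, area),
            )
        )
        bf = render_brightfield(scene, config.optics, noise_sd=sim.noise_sd_bf)
        fl = render_fluorescence(scene, config.optics, sim.condition, sim.staining,
                                 noise_sd=sim.noise_sd_fl)
        bf_dets = find_circles(bf, config.detection)
        fl_dets = find_circles(fl, config.detection)
        per_area.append(count_area(bf_dets, fl_dets))
        bf_all.append(bf_dets)
        truth_all.append(scene)
    return per_area, bf_all, truth_all


def dilution_series(
    conc_list: Sequence[float] = DEFAULT_DILUTION_SERIES,
    n_replicates: int = 3,
    config: PipelineConfig | None = None,
    seed: int = 0,
    classes: Sequence[str] = ("WBC", "RBC"),
) -> dict[str, DilutionSeriesResult]:
    """Measure a serial-dilution series for each cell class.

    Each (concentration, replicate) simulates one chamber: ``n_areas``
    settled frame pairs, detection in both modalities, subtraction
    counting, and concentration over the analysis volume.  Classes are run
    as separate suspensions (the other class at zero), as in a
    platform-characterization experiment.  Measured concentration is
    regressed on expected by ordinary least squares with intercept.
    """
    if len(set(conc_list)) < 2:
        raise ValidationError("conc_list", "needs >= 2 distinct concentrations")
    if n_replicates < 1:
        raise ValidationError("n_replicates", "must be >= 1")
    config = config or PipelineConfig()
    results: dict[str, DilutionSeriesResult] = {}
    for ci, cls in enumerate(classes):
        expected, measured = [], []
        points = []
        for ki, conc in enumerate(sorted(conc_list)):
            reps = []
            for rep in range(n_replicates):
                s = _sub_seed(seed, ci, ki, rep)
                c_rbc = conc if cls == "RBC" else 0.0
                c_wbc = conc if cls == "WBC" else 0.0
                per_area, _, _ = _measure_chamber(c_rbc, c_wbc, config, s)
                res = concentrations(per_area, config.chamber)
                reps.append(res.c_rbc if cls == "RBC" else res.c_wbc)
            reps = np.asarray(reps)
            mean, sd = float(reps.mean()), float(reps.std(ddof=1)) if len(reps) > 1 else 0.0
            points.append(DilutionPoint(
                expected_conc=float(conc), measured_mean=mean, measured_sd=sd,
                cv=sd / mean if mean > 0 else float("nan"),
            ))
            expected.extend([conc] * len(reps))
            measured.extend(reps.tolist())
        fit = stats.linregress(expected, measured)
        results[cls] = DilutionSeriesResult(
            points=tuple(points),
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue**2),
            cell_class=cls,
        )
    return results


@dataclass(frozen=True)
class AccuracyResult:
    """Agreement of automated counts with simulator ground truth."""

    mean_accuracy: float
    per_scene_accuracy: tuple[float, ...]
    f1: float
    precision: float
    recall: float
    n_scenes: int


def accuracy_vs_truth(
    n_scenes: int = 40,
    config: PipelineConfig | None = None,
    seed: int = 0,
    c_rbc: float = 100.0,
    c_wbc: float = 50.0,
    settle_cells: bool = True,
) -> AccuracyResult:
    """Counting accuracy and detection F1 over seeded synthetic scenes.

    Per scene, accuracy = 1 - |n_detected - n_true| / n_true for the total
    bright-field cell count (scenes with no true cells are skipped).  F1
    aggregates matches between bright-field detections and true in-band
    cell positions at a 3 μm tolerance over all scenes.
    """
    if n_scenes < 1:
        raise ValidationError("n_scenes", "must be >= 1")
    config = config or PipelineConfig()
    sim = config.simulator
    accs = []
    tp = fp = fn = 0
    for i in range(n_scenes):
        scene = sample_scene(
            c_rbc, c_wbc, config.optics, config.chamber,
            debris_rate=sim.debris_rate, clump_rate=sim.clump_rate,
            seed=_sub_seed(seed, 7, i),
        )
        if settle_cells:
            scene = settled(scene)
        bf = render_brightfield(scene, config.optics, noise_sd=sim.noise_sd_bf)
        dets = find_circles(bf, config.detection)
        truth_pts = scene.positions(("RBC", "WBC"))
        n_true = len(truth_pts)
        if n_true > 0:
            accs.append(max(0.0, 1.0 - abs(len(dets) - n_true) / n_true))
        m = match_detections(dets, [tuple(p) for p in truth_pts], tol=MATCH_TOL_UM)
        tp += m.n_matched
        fp += len(m.unmatched_a)
        fn += len(m.unmatched_b)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return AccuracyResult(
        mean_accuracy=float(np.mean(accs)) if accs else float("nan"),
        per_scene_accuracy=tuple(accs),
        f1=f1,
        precision=precision,
        recall=recall,
        n_scenes=n_scenes,
    )


def _pair_by_stem(bf_paths: Sequence[Path], fl_paths: Sequence[Path]) -> list[tuple[Path, Path]]:
    def stem_key(p: Path, suffix: str) -> str:
        return re.sub(rf"_{suffix}$", "", p.stem)

    bf_map = {stem_key(p, "bf"): p for p in bf_paths}
    fl_map = {stem_key(p, "fl"): p for p in fl_paths}
    if set(bf_map) == set(fl_map) and len(bf_map) == len(bf_paths):
        return [(bf_map[k], fl_map[k]) for k in sorted(bf_map)]
    if len(bf_paths) == len(fl_paths):
        logger.warning("file stems do not pair cleanly; falling back to positional order")
        return list(zip(bf_paths, fl_paths))
    orphans = sorted(set(bf_map) ^ set(fl_map))
    raise InputError(f"cannot pair bright-field and fluorescence inputs; orphans: {orphans}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    bf_paths: Sequence[str | Path],
    fl_paths: Sequence[str | Path],
    config: PipelineConfig | None = None,
) -> dict:
    """Detect, count, and report on paired bright-field/fluorescence frames.

    Returns a JSON-serializable report with per-area detections and counts,
    concentrations, CVs, parameters, warnings, input checksums, and stage
    timings.
    """
    config = config or PipelineConfig()
    bf_paths = [Path(p) for p in bf_paths]
    fl_paths = [Path(p) for p in fl_paths]
    if not bf_paths or not fl_paths:
        raise InputError("need at least one bright-field/fluorescence frame pair")
    pairs = _pair_by_stem(bf_paths, fl_paths)

    areas = []
    per_area_counts = []
    px = config.optics.pixel_size
    for bf_p, fl_p in pairs:
        t0 = time.perf_counter()
        bf = load_frame(bf_p, px, "bright_field")
        fl = load_frame(fl_p, px, "fluorescence")
        t_load = time.perf_counter()
        bf_dets = find_circles(bf, config.detection)
        fl_dets = find_circles(fl, config.detection)
        t_detect = time.perf_counter()
        ac = count_area(bf_dets, fl_dets)
        per_area_counts.append(ac)
        logger.info(
            "%s: %d bf / %d fl detections (load %.2fs, detect %.2fs)",
            bf_p.stem, len(bf_dets), len(fl_dets), t_load - t0, t_detect - t_load,
        )
        areas.append(
            {
                "bright_field": str(bf_p),
                "fluorescence": str(fl_p),
                "sha256_bf": _sha256(bf_p),
                "sha256_fl": _sha256(fl_p),
                "n_total": ac.n_total,
                "n_wbc": ac.n_wbc,
                "n_rbc": ac.n_rbc,
                "clamped": ac.clamped,
                "detections_bf": [
                    {"cx_um": d.cx, "cy_um": d.cy, "radius_um": d.radius, "score": d.score}
                    for d in bf_dets
                ],
                "detections_fl": [
                    {"cx_um": d.cx, "cy_um": d.cy, "radius_um": d.radius, "score": d.score}
                    for d in fl_dets
                ],
                "timings_s": {"load": t_load - t0, "detect": t_detect - t_load},
            }
        )

    result = concentrations(per_area_counts, config.chamber)

    def _nan_to_none(x: float):
        return None if x != x else x

    from .config import config_to_mapping

    return {
        "tool": "csfcount",
        "version": __version__,
        "areas": areas,
        "concentrations": {
            "c_wbc_per_ul": result.c_wbc,
            "c_rbc_per_ul": result.c_rbc,
            "c_total_per_ul": result.c_total,
        },
        "cv_across_areas": {
            "wbc": _nan_to_none(result.cv_wbc),
            "rbc": _nan_to_none(result.cv_rbc),
            "total": _nan_to_none(result.cv_total),
        },
        "analysis_volume_nl": result.analysis_volume,
        "warnings": {"clamping_events": result.clamping_warnings},
        "parameters": config_to_mapping(config),
    }


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
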