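"""End-to-end single-scan MEE pipeline.

Orchestrates the full analysis of one dynamic ¹¹C-acetate series:
image loading → automatic blood-pool extraction → plasma correction →
parametric imaging → LV segmentation → global washout fit → MVO₂ →
indicator-dilution cardiac output → MEE, with QC (motion heuristic,
skipped rays, fit flags) and a reproducibility fingerprint.  Every stage
is a pure function of its inputs and the configuration, so identical
configurations produce bit-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .efficiency import EfficiencyResult
from .hemodynamics import BolusDose, VitalsRecord, compute_fco, compute_map
from .image_io import DynamicImage, extract_tac, load_dynamic_series
from .input_functions import (InputFunctionSet, cluster_blood_pools,
                              isolate_first_pass, metabolite_correct,
                              parent_fraction_sigmoid)
from .kinetics import (BasisSet, fit_single_compartment, make_parametric_maps,
                       mvo2_from_k2)
from .segmentation import estimate_long_axis, find_slice_midpoints, segment_lv

__all__ = ["PipelineConfig", "MEEReport", "StageError", "run_mee_pipeline"]

log = logging.getLogger("acemee")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and QC context."""

    def __init__(self, stage: str, message: str, qc: dict | None = None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.qc = qc or {}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one MEE analysis."""

    image_path: str | None = None
    timing_path: str | None = None
    vitals_path: str | None = None
    dose_mbq: float | None = None
    # blood-pool clustering
    n_clusters: int = 6
    cluster_seed: int = 0
    early_window_min: float = 2.0
    # basis-function grid
    k2_min: float = 0.005
    k2_max: float = 1.0
    n_basis: int = 100
    # metabolite correction (parent-fraction model)
    metabolite_correction: dict = field(default_factory=lambda: {
        "model": "sigmoid", "t50_min": 12.0, "hill": 1.8})
    # indicator dilution
    fco_calibration: dict = field(default_factory=lambda: {"slope": 1.0, "intercept": 0.0})
    # segmentation
    va_threshold: float = 0.5
    # QC
    motion_threshold_mm: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def parent_fraction(self):
        mc = self.metabolite_correction
        model = mc.get("model", "sigmoid")
        if model == "none":
            return lambda t: np.ones_like(np.asarray(t, dtype=float))
        if model == "sigmoid":
            t50 = float(mc.get("t50_min", 12.0))
            hill = float(mc.get("hill", 1.8))
            return lambda t: parent_fraction_sigmoid(t, t50_min=t50, hill=hill)
        raise ValueError(f"unknown metabolite-correction model {model!r}")


@dataclass
class MEEReport:
    """Final result with intermediate artifacts and QC."""

    result: EfficiencyResult
    inputs: dict
    kinetics: dict
    segmentation: dict
    flow: dict
    qc: dict
    fingerprint: dict

    def to_dict(self) -> dict:
        return {"result": self.result.to_dict(), "inputs": self.inputs,
                "kinetics": self.kinetics, "segmentation": self.segmentation,
                "flow": self.flow, "qc": self.qc, "fingerprint": self.fingerprint}

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _motion_qc(image: DynamicImage, threshold_mm: float) -> dict:
    """Inter-frame centroid-shift heuristic over the stable late phase.

    The activity distribution legitimately migrates during the bolus
    transit, so only frames after 2 minutes are compared; a shift of the
    activity centroid beyond the threshold flags probable patient motion.
    """
    mid = image.schedule.mid_times
    late = np.flatnonzero(mid > 2.0)
    size = np.asarray(image.geometry.voxel_size)
    coords = [np.arange(n) * s for n, s in zip(image.spatial_shape, size)]
    centroids = []
    for f in late:
        frame = np.maximum(image.frame(int(f)), 0.0)
        total = frame.sum()
        if total <= 0:
            continue
        c = [float((frame.sum(axis=tuple(j for j in range(3) if j != ax))
                    * coords[ax]).sum() / total) for ax in range(3)]
        centroids.append(c)
    centroids = np.asarray(centroids)
    if centroids.size == 0:
        return {"max_shift_mm": float("nan"), "motion_suspected": False}
    ref = np.median(centroids, axis=0)
    shift = float(np.max(np.linalg.norm(centroids - ref, axis=1)))
    return {"max_shift_mm": shift, "motion_suspected": bool(shift > threshold_mm)}


def _fingerprint(config: PipelineConfig) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return {"software": "acemee", "version": __version__,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "cluster_seed": config.cluster_seed}


def run_mee_pipeline(config: PipelineConfig,
                     image: DynamicImage | None = None,
                     vitals: VitalsRecord | None = None,
                     dose_bq: float | None = None) -> MEEReport:
    """Run the full single-scan MEE analysis.

    ``image``, ``vitals`` and ``dose_bq`` may be passed in-memory; when
    omitted they are loaded from the paths in ``config``.
    """
    t_start = time.perf_counter()

    def stage(name):
        log.info("stage %-16s t=%.1fs", name, time.perf_counter() - t_start)

    stage("load")
    if image is None:
        if not (config.image_path and config.timing_path):
            raise StageError("load", "no image given and no paths configured")
        image = load_dynamic_series(config.image_path, config.timing_path)
    if vitals is None:
        if not config.vitals_path:
            raise StageError("load", "no vitals given and no vitals_path configured")
        vitals = VitalsRecord.from_csv(config.vitals_path)
    if dose_bq is None:
        if not config.dose_mbq:
            raise StageError("load", "no injected dose given")
        dose_bq = config.dose_mbq * 1e6

    qc: dict = {"n_negative_voxels": image.n_negative_voxels}
    qc["motion"] = _motion_qc(image, config.motion_threshold_mm)
    if qc["motion"]["motion_suspected"]:
        log.warning("possible patient motion: centroid shift %.1f mm",
                    qc["motion"]["max_shift_mm"])

    stage("input_functions")
    try:
        ifs = cluster_blood_pools(image, n_clusters=config.n_clusters,
                                  early_window_min=config.early_window_min,
                                  seed=config.cluster_seed)
    except Exception as exc:
        raise StageError("input_functions", str(exc), qc) from exc
    c_p = metabolite_correct(ifs.c_a, config.parent_fraction())
    ifs = InputFunctionSet(c_a=ifs.c_a, c_rv=ifs.c_rv, c_p=c_p, masks=ifs.masks)

    stage("parametric_maps")
    try:
        basis = BasisSet.build(c_p, image.schedule, k2_min=config.k2_min,
                               k2_max=config.k2_max, n=config.n_basis)
        frame_mean = image.values.mean(axis=3)
        body_mask = frame_mean > 0.05 * frame_mean.max()
        maps = make_parametric_maps(image, ifs, basis, body_mask)
    except Exception as exc:
        raise StageError("parametric_maps", str(exc), qc) from exc

    stage("segmentation")
    try:
        axis = estimate_long_axis(maps)
        cos_z = abs(float(axis[2]))
        qc["long_axis_cos_z"] = cos_z
        if cos_z < np.cos(np.deg2rad(15.0)):
            qc["short_axis_warning"] = True
            log.warning("LV long axis deviates %.0f deg from the slice normal; "
                        "slices do not look short-axis",
                        np.rad2deg(np.arccos(cos_z)))
        midpoints = find_slice_midpoints(maps, va_threshold=config.va_threshold)
        seg = segment_lv(maps, midpoints)
    except Exception as exc:
        raise StageError("segmentation", str(exc), qc) from exc
    qc["segmentation"] = seg.qc
    qc["n_voxel_fit_failures"] = maps.n_failed

    stage("global_fit")
    try:
        c_pet = extract_tac(image, seg.mask)
        params = fit_single_compartment(c_pet, ifs, basis)
        mvo2 = mvo2_from_k2(params.k2)
    except Exception as exc:
        raise StageError("global_fit", str(exc), qc) from exc

    stage("flow")
    try:
        peak = isolate_first_pass(ifs.c_a)
        cal = (config.fco_calibration.get("slope", 1.0),
               config.fco_calibration.get("intercept", 0.0))
        flow = compute_fco(BolusDose(dose_bq=dose_bq), peak, vitals.hr_mean,
                           calibration=cal)
    except Exception as exc:
        raise StageError("flow", str(exc), qc) from exc

    stage("efficiency")
    map_mmhg, map_source = compute_map(vitals)
    flags = params.flags + peak.flags
    if qc["motion"]["motion_suspected"]:
        flags += ("motion_suspected",)
    result = EfficiencyResult.assemble(
        map_mmhg=map_mmhg, fco_ml_min=flow.fco_ml_min, fsv_ml=flow.fsv_ml,
        mvo2=mvo2, lvm_g=seg.lvm_g, k2=params.k2, map_source=map_source,
        fco_calibration=flow.calibration, flags=flags)

    report = MEEReport(
        result=result,
        inputs={
            "c_a": ifs.c_a.values.tolist(), "c_rv": ifs.c_rv.values.tolist(),
            "c_p": ifs.c_p.values.tolist(), "times_min": ifs.c_a.times.tolist(),
            "dose_bq": dose_bq, "hr_mean": vitals.hr_mean,
        },
        kinetics={"k1": params.k1, "k2": params.k2, "v_a": params.v_a,
                  "v_v": params.v_v, "rss": params.rss, "mvo2": mvo2},
        segmentation={"lvm_g": seg.lvm_g, "volume_mm3": seg.volume_mm3,
                      "n_slices": len(seg.qc.get("segmented_slices", []))},
        flow={"fco_ml_min": flow.fco_ml_min, "fsv_ml": flow.fsv_ml,
              "raw_fco_ml_min": flow.raw_fco_ml_min, "peak_auc": flow.peak_auc,
              "first_pass_window_min": list(peak.window)},
        qc=qc,
        fingerprint=_fingerprint(config),
    )
    stage("done")
    return report
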