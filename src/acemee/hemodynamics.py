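"""Vitals handling, indicator-dilution cardiac output, and stroke volume.

Heart rate and blood pressure are measured 1 minute before and 1 and 5
minutes after tracer injection and averaged.  Forward cardiac output
follows the indicator-dilution principle, FCO = I / ∫C_A(t), where I is
the injected dose (Bq) and the denominator the area under the isolated
arterial first-pass peak (Bq·mL⁻¹·min); a site-specific linear
calibration can absorb scanner-dependent differences.  Forward stroke
volume is FCO divided by the averaged heart rate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .input_functions import FirstPassPeak

__all__ = ["VitalsRecord", "BolusDose", "FlowEstimate",
           "compute_map", "compute_fco"]

STANDARD_TIMEPOINTS_MIN = (-1.0, 1.0, 5.0)


@dataclass
class VitalsRecord:
    """Blood pressure and heart rate around tracer injection.

    ``map_mmhg`` entries are optional direct MAP measurements; when they
    are absent MAP is derived per timepoint as (SBP + 2·DBP)/3 and then
    averaged, and the result is flagged as derived.
    """

    timepoints_min: np.ndarray
    sbp_mmhg: np.ndarray
    dbp_mmhg: np.ndarray
    hr_min: np.ndarray
    map_mmhg: np.ndarray | None = None

    def __post_init__(self):
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
        self.sbp_mmhg = np.asarray(self.sbp_mmhg, dtype=float)
        self.dbp_mmhg = np.asarray(self.dbp_mmhg, dtype=float)
        self.hr_min = np.asarray(self.hr_min, dtype=float)
        n = self.timepoints_min.size
        for arr in (self.sbp_mmhg, self.dbp_mmhg, self.hr_min):
            if arr.size != n:
                raise ValueError("vitals arrays must share one length")
        if n == 0:
            raise ValueError("at least one vitals timepoint is required")
        if np.any(self.sbp_mmhg <= self.dbp_mmhg):
            raise ValueError("systolic pressure must exceed diastolic pressure")
        if np.any(self.dbp_mmhg <= 0) or np.any(self.hr_min <= 0):
            raise ValueError("pressures and heart rate must be positive")
        if self.map_mmhg is not None:
            self.map_mmhg = np.asarray(self.map_mmhg, dtype=float)
            if self.map_mmhg.size != n:
                raise ValueError("map_mmhg must match the other vitals arrays")

    @property
    def hr_mean(self) -> float:
        return float(np.mean(self.hr_min))

    @property
    def map_is_measured(self) -> bool:
        return self.map_mmhg is not None and np.all(np.isfinite(self.map_mmhg))

    @classmethod
    def from_csv(cls, path: str | Path) -> "VitalsRecord":
        """Read vitals from CSV with columns timepoint_min, sbp, dbp, hr[, map]."""
        rows = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                rows.append(row)
        if not rows:
            raise ValueError(f"no vitals rows in {path}")
        tp = [float(r["timepoint_min"]) for r in rows]
        sbp = [float(r["sbp"]) for r in rows]
        dbp = [float(r["dbp"]) for r in rows]
        hr = [float(r["hr"]) for r in rows]
        maps = None
        if all(r.get("map") not in (None, "", "NA") for r in rows):
            maps = [float(r["map"]) for r in rows]
        return cls(timepoints_min=np.array(tp), sbp_mmhg=np.array(sbp),
                   dbp_mmhg=np.array(dbp), hr_min=np.array(hr),
                   map_mmhg=None if maps is None else np.array(maps))


def compute_map(vitals: VitalsRecord) -> tuple[float, str]:
    """Averaged mean arterial pressure and its provenance.

    Directly measured MAP readings are averaged when available; otherwise
    the clinical fallback MAP = (SBP + 2·DBP)/3 is applied per timepoint
    before averaging and the result is labelled ``"derived"``.
    """
    if vitals.map_is_measured:
        return float(np.mean(vitals.map_mmhg)), "measured"
    per_tp = (vitals.sbp_mmhg + 2.0 * vitals.dbp_mmhg) / 3.0
    return float(np.mean(per_tp)), "derived"


@dataclass(frozen=True)
class BolusDose:
    """Injected ¹¹C-acetate dose."""

    dose_bq: float
    injection_time_min: float = 0.0

    def __post_init__(self):
        if self.dose_bq <= 0:
            raise ValueError("injected dose must be positive")


@dataclass
class FlowEstimate:
    fco_ml_min: float
    fsv_ml: float
    raw_fco_ml_min: float
    peak_auc: float
    calibration: tuple[float, float]

    def __post_init__(self):
        if self.fco_ml_min <= 0:
            raise ValueError("forward cardiac output must be positive")


def compute_fco(dose: BolusDose, peak: FirstPassPeak, hr_min: float,
                calibration: tuple[float, float] = (1.0, 0.0)) -> FlowEstimate:
    """Indicator-dilution forward cardiac output FCO = I / ∫C_A.

    ``calibration`` is a site-supplied linear map (slope, intercept)
    correcting scanner-dependent differences; the default is identity.
    FSV = FCO / HR.
    """
    if peak.auc <= 0:
        raise ValueError("first-pass AUC must be positive")
    if hr_min <= 0:
        raise ValueError("heart rate must be positive")
    raw = dose.dose_bq / peak.auc
    slope, intercept = calibration
    fco = slope * raw + intercept
    return FlowEstimate(fco_ml_min=fco, fsv_ml=fco / hr_min, raw_fco_ml_min=raw,
                        peak_auc=peak.auc, calibration=(float(slope), float(intercept)))
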