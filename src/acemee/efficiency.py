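"""Myocardial external efficiency and method-agreement statistics.

MEE is the energy balance of the left ventricle:

    MEE = EW / TE · 100%
    EW  = MAP · FCO · 1.33e−4      (external work, J)
    TE  = MVO₂ · LVM · 20          (total energy use, J)

with MAP in mmHg, FCO in mL·min⁻¹, MVO₂ in mL O₂·g⁻¹·min⁻¹ and LVM in
grams.  1.33e−4 converts mmHg·mL to J and 20 converts mL O₂ to J.  The
numbers are reported exactly in these conventional units even though the
products are per-minute quantities; healthy hearts run near 20–25%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EnergyTerms",
    "EfficiencyResult",
    "AgreementStats",
    "compute_ew",
    "compute_te",
    "compute_mee",
    "agreement",
    "MMHG_ML_TO_J",
    "ML_O2_TO_J",
]

MMHG_ML_TO_J = 1.33e-4
ML_O2_TO_J = 20.0


def compute_ew(map_mmhg: float, fco_ml_min: float) -> float:
    """External work EW = MAP·FCO·1.33e−4 (J)."""
    if map_mmhg <= 0 or fco_ml_min <= 0:
        raise ValueError("MAP and FCO must be positive")
    return map_mmhg * fco_ml_min * MMHG_ML_TO_J


def compute_te(mvo2: float, lvm_g: float) -> float:
    """Total energy use TE = MVO₂·LVM·20 (J)."""
    if mvo2 <= 0 or lvm_g <= 0:
        raise ValueError("MVO2 and LVM must be positive")
    return mvo2 * lvm_g * ML_O2_TO_J


def compute_mee(ew_j: float, te_j: float) -> float:
    """Myocardial external efficiency in percent."""
    if te_j <= 0:
        raise ValueError("total energy must be positive")
    return 100.0 * ew_j / te_j


@dataclass(frozen=True)
class EnergyTerms:
    ew_j: float
    te_j: float

    def __post_init__(self):
        if self.ew_j < 0 or self.te_j <= 0:
            raise ValueError("EW must be non-negative and TE positive")


@dataclass
class EfficiencyResult:
    """MEE with all of its inputs and provenance flags."""

    mee_pct: float
    ew_j: float
    te_j: float
    map_mmhg: float
    fco_ml_min: float
    fsv_ml: float
    mvo2: float
    lvm_g: float
    k2: float
    map_source: str = "measured"
    fco_calibration: tuple[float, float] = (1.0, 0.0)
    flags: tuple[str, ...] = ()

    @classmethod
    def assemble(cls, map_mmhg: float, fco_ml_min: float, fsv_ml: float,
                 mvo2: float, lvm_g: float, k2: float,
                 map_source: str = "measured",
                 fco_calibration: tuple[float, float] = (1.0, 0.0),
                 flags: tuple[str, ...] = ()) -> "EfficiencyResult":
        ew = compute_ew(map_mmhg, fco_ml_min)
        te = compute_te(mvo2, lvm_g)
        return cls(mee_pct=compute_mee(ew, te), ew_j=ew, te_j=te,
                   map_mmhg=map_mmhg, fco_ml_min=fco_ml_min, fsv_ml=fsv_ml,
                   mvo2=mvo2, lvm_g=lvm_g, k2=k2, map_source=map_source,
                   fco_calibration=fco_calibration, flags=flags)

    def to_dict(self) -> dict:
        return {
            "mee_pct": self.mee_pct, "ew_j": self.ew_j, "te_j": self.te_j,
            "map_mmhg": self.map_mmhg, "fco_ml_min": self.fco_ml_min,
            "fsv_ml": self.fsv_ml, "mvo2": self.mvo2, "lvm_g": self.lvm_g,
            "k2": self.k2, "map_source": self.map_source,
            "fco_calibration": list(self.fco_calibration),
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman style agreement between two methods.

    ``bias`` is mean(method1 − method2); ``rpc`` (repeatability
    coefficient) is 2 × the sample SD of the differences.
    """

    n: int
    r: float
    bias: float
    sd_diff: float
    rpc: float


def agreement(method1, method2) -> AgreementStats:
    """Pearson correlation, bias, SD of differences and RPC = 2·SD."""
    a = np.asarray(method1, dtype=float)
    b = np.asarray(method2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant method")
    r = float(stats.pearsonr(a, b).statistic)
    diff = a - b
    sd = float(np.std(diff, ddof=1))
    return AgreementStats(n=int(a.size), r=r, bias=float(np.mean(diff)),
                          sd_diff=sd, rpc=2.0 * sd)
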