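"""Single-tissue compartment kinetics with blood spillover.

The myocardial time–activity curve is modelled as

    C_PET(t) = (1 − V_A)·K1·[C_P ⊗ exp(−k2·t)](t) + V_A·C_A(t) + V_V·C_RV(t)

with K1 the ¹¹C-acetate uptake rate (mL·g⁻¹·min⁻¹), k2 the washout rate
(min⁻¹), V_A the arterial blood-volume/spillover fraction and V_V the
right-ventricular spillover fraction.  At fixed k2 the model is linear in
{(1−V_A)K1, V_A, V_V}; fitting therefore scans a grid of k2 values
(basis-function method), solving a small non-negative least-squares
problem at each grid point, and refines the winning k2 locally.

The oxygen-consumption calibration for acetate washout is

    MVO2 = 1.35·k2 − 9.6e−3   (mL O₂·g⁻¹·min⁻¹).

Convolutions are evaluated on a fine uniform time grid (default 1 s) with
a recursive exponential filter, then sampled at frame mid-times; frame
durations in a cardiac protocol span 5–300 s, so convolving on the frame
grid itself would be badly inaccurate during the bolus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar, nnls

from .image_io import DynamicImage, FrameSchedule, TimeActivityCurve, VoxelGeometry

__all__ = [
    "KineticParameters",
    "BasisSet",
    "ParametricMaps",
    "model_tac",
    "fit_single_compartment",
    "make_parametric_maps",
    "mvo2_from_k2",
    "MVO2_SLOPE",
    "MVO2_INTERCEPT",
]

MVO2_SLOPE = 1.35
MVO2_INTERCEPT = -9.6e-3

#: voxels whose fitted total blood fraction V_A + V_V exceeds this are
#: classified as blood and carry K1 = 0 in the parametric map
BLOOD_FRACTION_CUTOFF = 0.8

DEFAULT_FINE_DT_MIN = 1.0 / 60.0  # 1 s


@dataclass
class KineticParameters:
    """Fitted parameters of the one-tissue model with spillover."""

    k1: float
    k2: float
    v_a: float
    v_v: float
    rss: float = np.nan
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("rate constants must be non-negative")
        if not (0.0 <= self.v_a <= 1.0 and 0.0 <= self.v_v <= 1.0):
            raise ValueError("blood fractions must lie in [0, 1]")
        if self.v_a + self.v_v > 1.0 + 1e-9:
            raise ValueError("V_A + V_V must not exceed 1")


def _fine_grid(schedule: FrameSchedule, dt: float) -> np.ndarray:
    t_end = float(schedule.end_times[-1])
    n = int(np.ceil(t_end / dt)) + 1
    return np.arange(n) * dt


def _interp_curve(curve: TimeActivityCurve, t_fine: np.ndarray) -> np.ndarray:
    # Activity is zero at injection time; anchor the interpolant there.
    t = np.concatenate([[0.0], curve.times])
    v = np.concatenate([[0.0], curve.values])
    if curve.times[0] <= 0:
        t, v = curve.times, curve.values
    return np.interp(t_fine, t, v)


def conv_exp(values_fine: np.ndarray, dt: float, k2: float) -> np.ndarray:
    """Trapezoidal recursive evaluation of ∫ v(s)·exp(−k2·(t−s)) ds on a uniform grid."""
    e = np.exp(-k2 * dt)
    out = np.empty_like(values_fine)
    out[0] = 0.0
    half = dt / 2.0
    prev = 0.0
    # recursion: y[i] = e*y[i-1] + dt/2*(v[i] + e*v[i-1])
    for i in range(1, values_fine.size):
        prev = e * prev + half * (values_fine[i] + e * values_fine[i - 1])
        out[i] = prev
    return out


def _conv_exp_vec(values_fine: np.ndarray, dt: float, k2: float) -> np.ndarray:
    """Vectorised form of :func:`conv_exp` using a scaled cumulative sum."""
    n = values_fine.size
    e = np.exp(-k2 * dt)
    # increments g[i] = dt/2*(v[i] + e*v[i-1]) for i>=1; y[i] = sum_j e^(i-j) g[j]
    g = np.empty(n)
    g[0] = 0.0
    g[1:] = dt / 2.0 * (values_fine[1:] + e * values_fine[:-1])
    if k2 * dt * n < 500:  # safe to expand without underflow trouble
        powers = e ** np.arange(n)
        with np.errstate(over="ignore", invalid="ignore"):
            scaled = np.cumsum(g / np.where(powers > 0, powers, 1.0))
            y = scaled * powers
        if np.all(np.isfinite(y)):
            return y
    return conv_exp(values_fine, dt, k2)


@dataclass
class BasisSet:
    """Precomputed convolutions C_P ⊗ exp(−k2·t) over a grid of k2 values.

    ``basis`` holds one row per grid point, sampled at frame mid-times.
    The fine-grid plasma input is cached so that local k2 refinement can
    evaluate off-grid convolutions consistently.
    """

    k2_grid: np.ndarray
    basis: np.ndarray
    schedule: FrameSchedule
    cp_fine: np.ndarray
    t_fine: np.ndarray
    dt: float

    def __post_init__(self):
        self.k2_grid = np.asarray(self.k2_grid, dtype=float)
        if not (np.all(np.diff(self.k2_grid) > 0) and np.all(self.k2_grid > 0)):
            raise ValueError("k2 grid must be strictly increasing and positive")
        if self.basis.shape != (self.k2_grid.size, self.schedule.n_frames):
            raise ValueError("basis shape must be (n_k2, n_frames)")

    @classmethod
    def build(cls, cp: TimeActivityCurve, schedule: FrameSchedule,
              k2_min: float = 0.005, k2_max: float = 1.0, n: int = 100,
              dt: float = DEFAULT_FINE_DT_MIN) -> "BasisSet":
        k2_grid = np.geomspace(k2_min, k2_max, n)
        t_fine = _fine_grid(schedule, dt)
        cp_fine = _interp_curve(cp, t_fine)
        mid = schedule.mid_times
        basis = np.empty((n, schedule.n_frames))
        for i, k2 in enumerate(k2_grid):
            conv = _conv_exp_vec(cp_fine, dt, k2)
            basis[i] = np.interp(mid, t_fine, conv)
        return cls(k2_grid=k2_grid, basis=basis, schedule=schedule,
                   cp_fine=cp_fine, t_fine=t_fine, dt=dt)

    def row_at(self, k2: float) -> np.ndarray:
        """Convolution row for an arbitrary (off-grid) k2."""
        conv = _conv_exp_vec(self.cp_fine, self.dt, k2)
        return np.interp(self.schedule.mid_times, self.t_fine, conv)


@dataclass
class ParametricMaps:
    """Voxelwise maps of the fitted kinetic parameters."""

    k1: np.ndarray
    k2: np.ndarray
    v_a: np.ndarray
    v_v: np.ndarray
    rss: np.ndarray
    geometry: VoxelGeometry
    n_failed: int = 0

    def __post_init__(self):
        shapes = {m.shape for m in (self.k1, self.k2, self.v_a, self.v_v, self.rss)}
        if len(shapes) != 1:
            raise ValueError("parameter maps must share one shape")


def model_tac(params: KineticParameters, inputs, schedule: FrameSchedule,
              dt: float = DEFAULT_FINE_DT_MIN) -> TimeActivityCurve:
    """Forward one-tissue model evaluated at frame mid-times.

    ``inputs`` is an :class:`~acemee.input_functions.InputFunctionSet`
    (or any object with ``c_p``, ``c_a`` and ``c_rv`` curves).
    """
    if inputs.c_p is None:
        raise ValueError("plasma input C_P is required (run metabolite correction first)")
    t_fine = _fine_grid(schedule, dt)
    cp_fine = _interp_curve(inputs.c_p, t_fine)
    conv = _conv_exp_vec(cp_fine, dt, params.k2)
    mid = schedule.mid_times
    tissue = (1.0 - params.v_a) * params.k1 * np.interp(mid, t_fine, conv)
    vals = tissue + params.v_a * inputs.c_a.values + params.v_v * inputs.c_rv.values
    return TimeActivityCurve.from_schedule(schedule, vals)


def _coeffs_to_params(coef: np.ndarray, k2: float, rss: float,
                      flags: tuple[str, ...]) -> KineticParameters:
    c0, va, vv = (float(c) for c in coef)
    va = min(max(va, 0.0), 1.0)
    vv = min(max(vv, 0.0), 1.0)
    total = va + vv
    if total > 1.0:  # project onto the simplex edge
        va, vv = va / total, vv / total
        flags = flags + ("blood_fraction_projected",)
    k1 = c0 / (1.0 - va) if (1.0 - va) > 1e-9 else 0.0
    return KineticParameters(k1=k1, k2=float(k2), v_a=va, v_v=vv, rss=rss, flags=flags)


def _frame_weights(schedule: FrameSchedule, weights) -> np.ndarray:
    """Per-frame least-squares weights.

    ``"duration"`` whitens the duration-dependent part of rebinned frame
    noise (variance ∝ activity/duration), ``"none"`` is ordinary LS, and
    an array gives custom weights.
    """
    if isinstance(weights, str):
        if weights == "duration":
            return np.sqrt(schedule.durations)
        if weights == "none":
            return np.ones(schedule.n_frames)
        raise ValueError(f"unknown weighting scheme {weights!r}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (schedule.n_frames,) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per frame")
    return w


def fit_single_compartment(tac: TimeActivityCurve, inputs, basis: BasisSet,
                           weights: str | np.ndarray = "duration",
                           refine: bool = True) -> KineticParameters:
    """Basis-function fit of the one-tissue model to a single TAC.

    For every k2 grid point the coefficients {(1−V_A)K1, V_A, V_V} are
    obtained by non-negative least squares against {basis row, C_A, C_RV};
    the grid point with minimal residual sum of squares wins and k2 is
    refined by bounded scalar minimisation between its grid neighbours.
    Frames are weighted per :func:`_frame_weights` (the reported rss is
    the weighted objective).
    """
    y = np.asarray(tac.values, dtype=float)
    if y.shape != basis.schedule.mid_times.shape:
        raise ValueError("TAC and basis set do not share a schedule")
    w = _frame_weights(basis.schedule, weights)
    y = y * w
    ca = inputs.c_a.values * w
    crv = inputs.c_rv.values * w
    if not (np.any(ca) or np.any(crv) or np.any(basis.basis)):
        raise ValueError("degenerate design: all regressors are zero")

    def solve_at(row: np.ndarray) -> tuple[np.ndarray, float]:
        X = np.column_stack([row * w, ca, crv])
        coef, resid = nnls(X, y)
        return coef, resid ** 2

    rss_grid = np.empty(basis.k2_grid.size)
    coefs = np.empty((basis.k2_grid.size, 3))
    for i in range(basis.k2_grid.size):
        coefs[i], rss_grid[i] = solve_at(basis.basis[i])
    best = int(np.argmin(rss_grid))

    flags: tuple[str, ...] = ()
    if best in (0, basis.k2_grid.size - 1):
        flags += ("k2_grid_boundary",)

    k2_best = basis.k2_grid[best]
    coef_best, rss_best = coefs[best], rss_grid[best]
    if refine and 0 < best < basis.k2_grid.size - 1:
        lo, hi = basis.k2_grid[best - 1], basis.k2_grid[best + 1]

        def objective(log_k2: float) -> float:
            return solve_at(basis.row_at(np.exp(log_k2)))[1]

        res = minimize_scalar(objective, bounds=(np.log(lo), np.log(hi)),
                              method="bounded", options={"xatol": 1e-4})
        if res.fun <= rss_best:
            k2_best = float(np.exp(res.x))
            coef_best, rss_best = solve_at(basis.row_at(k2_best))
    return _coeffs_to_params(coef_best, k2_best, float(rss_best), flags)


# ---------------------------------------------------------------------------
# Vectorised voxelwise fitting

_SUBSETS = [(0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)]


def _nnls3_stacked(G: np.ndarray, B: np.ndarray, yy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact 3-variable NNLS for many right-hand sides sharing one design.

    G is the 3×3 Gram matrix XᵀX, B the stacked XᵀY of shape (3, n) and
    yy the per-column ‖y‖².  Enumerates the seven non-empty active sets:
    each feasible subset solution, padded with zeros, is feasible for the
    full problem, and the optimal active set appears among them, so the
    feasible candidate with minimal RSS is the exact NNLS optimum.
    """
    n = B.shape[1]
    best_rss = yy.copy()  # empty active set: all coefficients zero
    best_coef = np.zeros((3, n))
    for S in _SUBSETS:
        idx = np.asarray(S)
        GS = G[np.ix_(idx, idx)]
        try:
            GS_inv = np.linalg.inv(GS)
        except np.linalg.LinAlgError:
            continue
        cS = GS_inv @ B[idx]                       # (|S|, n)
        feasible = np.all(cS >= 0, axis=0)
        quad = np.einsum("in,ij,jn->n", cS, GS, cS)
        rss = yy - 2.0 * np.einsum("in,in->n", cS, B[idx]) + quad
        better = feasible & (rss < best_rss)
        if np.any(better):
            best_rss[better] = rss[better]
            coef_full = np.zeros((3, n))
            coef_full[idx] = cS
            best_coef[:, better] = coef_full[:, better]
    return best_coef, best_rss


def make_parametric_maps(image: DynamicImage, inputs, basis: BasisSet,
                         body_mask: np.ndarray,
                         blood_fraction_cutoff: float = BLOOD_FRACTION_CUTOFF,
                         weights: str | np.ndarray = "duration",
                         refine: bool = True) -> ParametricMaps:
    """Voxelwise basis-function fit inside ``body_mask``.

    Voxels outside the mask are zero-filled.  k2 is refined per voxel by
    parabolic interpolation of the RSS profile in log k2 around the best
    grid point.  Voxels whose fitted total blood fraction exceeds
    ``blood_fraction_cutoff`` are classified as blood and report K1 = 0
    (the tissue-fraction normalisation K1 = c0/(1−V_A) is meaningless in
    near-pure blood).
    """
    body_mask = np.asarray(body_mask).astype(bool)
    if body_mask.shape != image.spatial_shape:
        raise ValueError("body mask shape mismatch")
    if not body_mask.any():
        raise ValueError("body mask is empty")

    w = _frame_weights(image.schedule, weights)
    Y = image.values[body_mask].T * w[:, None]  # (n_frames, n_vox), whitened
    n_vox = Y.shape[1]
    yy = np.einsum("fn,fn->n", Y, Y)
    ca = inputs.c_a.values * w
    crv = inputs.c_rv.values * w
    bY_ca = ca @ Y
    bY_crv = crv @ Y

    n_k2 = basis.k2_grid.size
    rss_all = np.empty((n_k2, n_vox))
    coef_all = np.empty((n_k2, 3, n_vox))
    for i in range(n_k2):
        row = basis.basis[i] * w
        X = np.column_stack([row, ca, crv])
        G = X.T @ X
        B = np.vstack([row @ Y, bY_ca, bY_crv])
        coef_all[i], rss_all[i] = _nnls3_stacked(G, B, yy)

    best = np.argmin(rss_all, axis=0)
    cols = np.arange(n_vox)
    coef = coef_all[best, :, cols].T  # (3, n_vox)
    rss = rss_all[best, cols]
    k2 = basis.k2_grid[best]

    if refine:
        interior = (best > 0) & (best < n_k2 - 1)
        if np.any(interior):
            b = best[interior]
            c = cols[interior]
            x0 = np.log(basis.k2_grid[b - 1])
            x1 = np.log(basis.k2_grid[b])
            x2 = np.log(basis.k2_grid[b + 1])
            f0 = rss_all[b - 1, c]
            f1 = rss_all[b, c]
            f2 = rss_all[b + 1, c]
            denom = (f0 - f1) * (x1 - x2) - (f1 - f2) * (x0 - x1)
            with np.errstate(divide="ignore", invalid="ignore"):
                vertex = 0.5 * ((f0 - f1) * (x1 ** 2 - x2 ** 2)
                                - (f1 - f2) * (x0 ** 2 - x1 ** 2)) / denom
            # fall back to the grid point for flat/degenerate parabolas
            bad = ~np.isfinite(vertex) | (vertex < x0) | (vertex > x2)
            vertex[bad] = x1[bad]
            k2_ref = k2.copy()
            k2_ref[interior] = np.exp(vertex)
            k2 = k2_ref

    c0, va_r, vv_r = coef
    va = np.clip(va_r, 0.0, 1.0)
    vv = np.clip(vv_r, 0.0, 1.0)
    total = va + vv
    over = total > 1.0
    va[over] /= total[over]
    vv[over] /= total[over]
    tissue_frac = 1.0 - va
    with np.errstate(divide="ignore", invalid="ignore"):
        k1 = np.where(tissue_frac > 1e-9, c0 / np.maximum(tissue_frac, 1e-9), 0.0)
    blood = (va + vv) > blood_fraction_cutoff
    k1 = np.where(blood, 0.0, k1)

    failed = ~np.isfinite(rss)
    n_failed = int(np.count_nonzero(failed))
    for arr in (k1, k2, va, vv):
        arr[failed] = 0.0
    rss = np.where(failed, 0.0, rss)

    def scatter(flat: np.ndarray) -> np.ndarray:
        out = np.zeros(image.spatial_shape)
        out[body_mask] = flat
        return out

    return ParametricMaps(k1=scatter(k1), k2=scatter(np.where(blood, 0.0, k2)),
                          v_a=scatter(va), v_v=scatter(vv), rss=scatter(rss),
                          geometry=image.geometry, n_failed=n_failed)


def mvo2_from_k2(k2):
    """Oxygen consumption (mL O₂·g⁻¹·min⁻¹) from the acetate washout rate.

    MVO2 = 1.35·k2 − 9.6e−3.  Small negative outputs are possible for
    k2 below the calibration range and are returned as-is with a warning.
    """
    k2 = np.asarray(k2, dtype=float)
    if np.any(k2 < 0):
        raise ValueError("k2 must be non-negative")
    mvo2 = MVO2_SLOPE * k2 + MVO2_INTERCEPT
    if np.any(mvo2 < 0):
        warnings.warn("MVO2 below zero: k2 is outside the calibration range",
                      RuntimeWarning, stacklevel=2)
    return float(mvo2) if mvo2.ndim == 0 else mvo2
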