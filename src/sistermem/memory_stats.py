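"""Pair-correlation and difference-variance statistics for lineage pairs.

Implements the memory measures of the sisters-machine analysis:

* the pair Pearson correlation function (PCF): the correlation, across an
  ensemble of aligned cell pairs, of a property's values at matched
  generation or time.  Because pair members are unordered, the estimator is
  symmetrised over the two orderings (an intraclass-style Pearson with the
  1/n population normalisation).  By convention the value at the alignment
  origin is 1 (the two members are literally the same mother cell there);
  measured correlations start at generation 1, the first full
  post-alignment cycle.
* the per-lineage autocorrelation function (ACF) at integer generation
  lags, pooled across lineages or reported per trap;
* windowed instantaneous elongation rates alpha(t) = d ln L / dt estimated
  by least squares over a short moving window inside one cycle;
* pairwise difference series delta_y(t) = y1(t) - y2(t) and their
  across-pair variance dynamics with plateau (saturation) metrics;
* single-exponential memory fits A exp(-lambda g) with half-life
  ln 2 / lambda;
* bootstrap standard errors by resampling pairs with replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .lineage_data import CellCycle, Lineage, PairEnsemble

__all__ = [
    "DegenerateDataError",
    "FitError",
    "ExponentialFit",
    "CorrelationSeries",
    "DeltaSeries",
    "VarianceSeries",
    "PairDifferenceSummary",
    "pcf",
    "pcf_series",
    "pcf_time",
    "acf",
    "acf_series",
    "windowed_alpha",
    "delta_series",
    "variance_series",
    "variance_by_generation",
    "saturation_metrics",
    "fit_exponential",
    "fit_series",
    "pair_rate_difference_summary",
    "bootstrap_se",
]


class DegenerateDataError(ValueError):
    """A correlation was requested on data with zero variance."""


class FitError(RuntimeError):
    """Exponential fit failed; residuals (if any) are in ``residuals``."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


NON_DECAYING = float("inf")
_LAMBDA_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExponentialFit:
    amplitude: float
    decay_rate: float        # per grid unit (generation or minute)
    half_life: float         # ln2/decay_rate; inf if non-decaying
    n_points: int
    rmse: float

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "decay_rate": self.decay_rate,
            "half_life": None if math.isinf(self.half_life) else self.half_life,
            "n_points": self.n_points,
            "rmse": self.rmse,
        }


@dataclass
class CorrelationSeries:
    grid: np.ndarray            # generations or minutes
    values: np.ndarray          # correlations, in [-1, 1]
    se: np.ndarray | None
    n_pairs: np.ndarray
    kind: str                   # 'generation' | 'time'
    origin_convention: bool = True
    fit: ExponentialFit | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "grid": self.grid, "value": self.values,
            "se": self.se if self.se is not None else np.nan,
            "n_pairs": self.n_pairs,
        })


@dataclass
class DeltaSeries:
    grid_min: np.ndarray        # minutes since the alignment origin
    deltas: np.ndarray          # (n_pairs, n_grid), NaN where unobserved
    property: str               # 'alpha' | 'fluor'
    pair_type: str

    @property
    def n_pairs(self) -> int:
        return self.deltas.shape[0]


@dataclass
class VarianceSeries:
    grid: np.ndarray
    var: np.ndarray             # smoothed variance
    var_raw: np.ndarray
    n_pairs: np.ndarray
    smooth_window: int
    saturation_value: float
    saturation_time: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "grid": self.grid, "var": self.var, "var_raw": self.var_raw,
            "n_pairs": self.n_pairs,
        })


@dataclass
class PairDifferenceSummary:
    samples_sc: np.ndarray      # |mean rate difference| per SC pair
    samples_rp: np.ndarray
    sd_sc: float
    sd_rp: float

    @property
    def ratio(self) -> float:
        return self.sd_sc / self.sd_rp if self.sd_rp > 0 else float("nan")


# ---------------------------------------------------------------------------
# core estimators
# ---------------------------------------------------------------------------


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise population Pearson correlation of two (B, n) arrays."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc * xc).mean(axis=1))
    sy = np.sqrt((yc * yc).mean(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).mean(axis=1) / denom
    r[denom == 0] = np.nan
    return r


def symmetric_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation symmetrised over pair orderings.

    Each pair contributes both (x, y) and (y, x); means and SDs are taken
    over the pooled contributing values (population, 1/n normalisation).
    Raises :class:`DegenerateDataError` on zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xs = np.concatenate([x, y])[None, :]
    ys = np.concatenate([y, x])[None, :]
    r = _pearson_rows(xs, ys)[0]
    if np.isnan(r):
        raise DegenerateDataError("zero variance; correlation undefined")
    return float(np.clip(r, -1.0, 1.0))


def _prop_value(cycle: CellCycle, prop: str) -> float:
    if prop == "T":
        return cycle.T
    if prop == "alpha":
        return cycle.alpha_cycle
    if prop in ("length", "L_birth"):
        return cycle.L_birth
    if prop == "L_div":
        return cycle.L_div
    if prop in ("fluor", "f_mean"):
        return cycle.f_mean
    raise ValueError(f"unknown property {prop!r}")


def _pair_values_at_g(ensemble: PairEnsemble, prop: str, g: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (left, right) property values at generation g >= 1."""
    xs, ys = [], []
    for p in ensemble.pairs:
        idx = g - 1  # generation 1 is each member's first full cycle
        if idx < len(p.left.cycles) and idx < len(p.right.cycles):
            a = _prop_value(p.left.cycles[idx], prop)
            b = _prop_value(p.right.cycles[idx], prop)
            if np.isfinite(a) and np.isfinite(b):
                xs.append(a)
                ys.append(b)
    return np.array(xs), np.array(ys)


def pcf(ensemble: PairEnsemble, prop: str, g: int) -> float:
    """Pair Pearson correlation of a property at generation ``g``.

    ``g = 0`` is the alignment origin and returns 1 exactly (the
    convention: at time zero the pair members coincide or are aligned by
    construction).  For ``g >= 1`` the symmetrised Pearson correlation
    across pairs of the generation-g values is returned; at least 3 pairs
    are required.
    """
    if g == 0:
        return 1.0
    x, y = _pair_values_at_g(ensemble, prop, g)
    if len(x) < 3:
        raise ValueError(f"fewer than 3 pairs with {prop!r} defined at generation {g}")
    return symmetric_pearson(x, y)


def bootstrap_se(
    statistic,
    n: int,
    n_boot: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Bootstrap SE of a pair-ensemble statistic.

    ``statistic(indices)`` must evaluate the statistic on the pairs selected
    by ``indices`` (with repetition) and return a float or array.  Returns
    the elementwise SD over ``n_boot`` seeded replicates (NaN replicates are
    ignored per element).
    """
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps.append(np.asarray(statistic(idx), dtype=float))
    return np.nanstd(np.stack(reps), axis=0)


def _bootstrap_corr_se(x: np.ndarray, y: np.ndarray, n_boot: int,
                       rng: np.random.Generator) -> float:
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xs = np.concatenate([x[idx], y[idx]], axis=1)
    ys = np.concatenate([y[idx], x[idx]], axis=1)
    r = _pearson_rows(xs, ys)
    return float(np.nanstd(r))


def pcf_series(
    ensemble: PairEnsemble,
    prop: str,
    g_max: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    fit_g_max: float | None = None,
) -> CorrelationSeries:
    """PCF of a per-cycle property on the generation grid 0..g_max.

    Grid point 0 carries the conventional value 1 (SE 0); points 1..g_max
    are measured.  Generations with fewer than 3 contributing pairs are
    NaN.  A single-exponential fit over the measured points is attached.
    """
    rng = np.random.default_rng(seed)
    grid = np.arange(g_max + 1, dtype=float)
    values = np.full(g_max + 1, np.nan)
    se = np.full(g_max + 1, np.nan)
    npairs = np.zeros(g_max + 1, dtype=int)
    values[0], se[0], npairs[0] = 1.0, 0.0, ensemble.n
    for g in range(1, g_max + 1):
        x, y = _pair_values_at_g(ensemble, prop, g)
        npairs[g] = len(x)
        if len(x) < 3:
            continue
        try:
            values[g] = symmetric_pearson(x, y)
        except DegenerateDataError:
            continue
        if n_boot:
            se[g] = _bootstrap_corr_se(x, y, n_boot, rng)
    series = CorrelationSeries(grid, values, se, npairs, "generation",
                               origin_convention=True)
    try:
        series.fit = fit_series(series, x_max=fit_g_max if fit_g_max is not None else g_max)
    except FitError:
        series.fit = None
    return series


def _frame_trace(lineage: Lineage, prop: str) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated per-frame (time, value) trace along a lineage."""
    ts, vs = [], []
    for c in lineage.cycles:
        ts.append(c.times)
        vs.append(c.lengths if prop == "length" else c.fluors)
    return np.concatenate(ts), np.concatenate(vs)


def _rel_matrix(
    ensemble: PairEnsemble,
    trace_fn,
    dt: float,
    t_max: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align member traces on the shared relative-frame grid.

    ``trace_fn(lineage)`` returns (times, values).  Returns (grid_min,
    left_matrix, right_matrix) with NaN where unobserved.
    """
    traces = []
    k_last = 0
    for p in ensemble.pairs:
        ta, va = trace_fn(p.left)
        tb, vb = trace_fn(p.right)
        ka = np.round((ta - p.t0_left) / dt).astype(int)
        kb = np.round((tb - p.t0_right) / dt).astype(int)
        traces.append((ka, va, kb, vb))
        if len(ka):
            k_last = max(k_last, ka.max())
        if len(kb):
            k_last = max(k_last, kb.max())
    if t_max is not None:
        k_last = min(k_last, int(t_max / dt))
    K = k_last + 1
    left = np.full((len(traces), K), np.nan)
    right = np.full((len(traces), K), np.nan)
    for i, (ka, va, kb, vb) in enumerate(traces):
        ma = (ka >= 0) & (ka < K)
        mb = (kb >= 0) & (kb < K)
        left[i, ka[ma]] = va[ma]
        right[i, kb[mb]] = vb[mb]
    return np.arange(K) * dt, left, right


def _infer_dt_ensemble(ensemble: PairEnsemble) -> float:
    for p in ensemble.pairs:
        t = p.left.cycles[0].times
        if len(t) > 1:
            return float(t[1] - t[0])
    raise ValueError("cannot infer frame interval from ensemble")


def pcf_time(
    ensemble: PairEnsemble,
    prop: str = "length",
    smooth_frames: int = 6,
    t_max: float | None = None,
    n_boot: int = 500,
    seed: int = 0,
    min_pairs: int = 3,
    fit_t_max: float | None = None,
) -> CorrelationSeries:
    """Time-resolved PCF of a per-frame property (default: cell length).

    The correlation is computed per relative frame on the pairs' common
    time grid and then boxcar-averaged over ``smooth_frames`` consecutive
    frames.  Grid point 0 carries the conventional value 1 and is excluded
    from smoothing and fitting.
    """
    dt = _infer_dt_ensemble(ensemble)
    rng = np.random.default_rng(seed)
    grid, left, right = _rel_matrix(ensemble, lambda lin: _frame_trace(lin, prop),
                                    dt, t_max)
    K = len(grid)
    values = np.full(K, np.nan)
    se = np.full(K, np.nan)
    npairs = np.zeros(K, dtype=int)
    values[0], se[0], npairs[0] = 1.0, 0.0, ensemble.n
    for k in range(1, K):
        ok = ~np.isnan(left[:, k]) & ~np.isnan(right[:, k])
        npairs[k] = int(ok.sum())
        if npairs[k] < min_pairs:
            continue
        x, y = left[ok, k], right[ok, k]
        try:
            values[k] = symmetric_pearson(x, y)
        except DegenerateDataError:
            continue
        if n_boot:
            se[k] = _bootstrap_corr_se(x, y, n_boot, rng)
    if smooth_frames > 1:
        sm = pd.Series(values[1:]).rolling(
            smooth_frames, center=True, min_periods=1).mean().to_numpy()
        values = np.concatenate([[1.0], sm])
    series = CorrelationSeries(grid, values, se, npairs, "time",
                               origin_convention=True)
    try:
        series.fit = fit_series(series, x_max=fit_t_max)
    except FitError:
        series.fit = None
    return series


def acf(lineages: list[Lineage], prop: str, lag: int) -> float:
    """Lag-g autocorrelation of a per-cycle property pooled over lineages."""
    if lag < 0:
        raise ValueError("lag must be >= 0")
    xs, ys = [], []
    for lin in lineages:
        y = np.array([_prop_value(c, prop) for c in lin.cycles])
        if len(y) > lag:
            xs.append(y[: len(y) - lag])
            ys.append(y[lag:])
    if not xs:
        raise ValueError("no lineage longer than the requested lag")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    r = _pearson_rows(x[None, :], y[None, :])[0]
    if np.isnan(r):
        raise DegenerateDataError("zero variance; ACF undefined")
    return float(np.clip(r, -1.0, 1.0))


def acf_per_trap(lineages: list[Lineage], prop: str, lag: int) -> dict[str, float]:
    """ACF computed separately per trap, to exhibit trap-to-trap diversity."""
    out = {}
    by_trap: dict[str, list[Lineage]] = {}
    for lin in lineages:
        by_trap.setdefault(lin.trap_id, []).append(lin)
    for trap in sorted(by_trap):
        try:
            out[trap] = acf(by_trap[trap], prop, lag)
        except (ValueError, DegenerateDataError):
            continue
    return out


def acf_series(lineages: list[Lineage], prop: str, max_lag: int = 10) -> CorrelationSeries:
    grid = np.arange(max_lag + 1, dtype=float)
    values = np.full(max_lag + 1, np.nan)
    for lag in range(max_lag + 1):
        try:
            values[lag] = acf(lineages, prop, lag)
        except (ValueError, DegenerateDataError):
            continue
    series = CorrelationSeries(grid, values, None, np.zeros_like(grid, dtype=int),
                               "generation", origin_convention=False)
    try:
        series.fit = fit_series(series, x_max=max_lag)
    except FitError:
        series.fit = None
    return series


# ---------------------------------------------------------------------------
# windowed elongation rate and difference series
# ---------------------------------------------------------------------------


def windowed_alpha(
    times: np.ndarray,
    lengths: np.ndarray,
    window_min: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous elongation rate over a moving window inside one cycle.

    At each frame whose full window [t - w/2, t + w/2] lies inside the
    cycle, returns the least-squares slope of ln(length) against time over
    the frames in the window.  Windows never cross a division because the
    input is a single cycle's frames.
    """
    times = np.asarray(times, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if len(times) < 2:
        return np.empty(0), np.empty(0)
    dt = times[1] - times[0]
    k = int(round(window_min / (2.0 * dt)))
    if 2 * k + 1 < 2:
        raise ValueError("window must span at least 2 frames")
    if len(times) < 2 * k + 1:
        return np.empty(0), np.empty(0)
    y = np.log(lengths)
    offsets = np.arange(-k, k + 1) * dt
    denom = float(np.dot(offsets, offsets))
    weights = offsets / denom
    # slope at center i = sum_j weights[j] * y[i + j - k] (sliding dot product)
    slopes = np.correlate(y, weights, mode="valid")
    return times[k:-k], slopes


def lineage_alpha_trace(lineage: Lineage, window_min: float = 6.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Windowed-alpha trace along a lineage (per cycle, concatenated)."""
    ts, vs = [], []
    for c in lineage.cycles:
        t, a = windowed_alpha(c.times, c.lengths, window_min)
        ts.append(t)
        vs.append(a)
    if not ts:
        return np.empty(0), np.empty(0)
    return np.concatenate(ts), np.concatenate(vs)


def delta_series(
    ensemble: PairEnsemble,
    prop: str = "alpha",
    window_min: float = 6.0,
    t_max: float | None = None,
) -> DeltaSeries:
    """Per-pair signed difference of a per-frame observable.

    ``prop='alpha'`` differences 6-min windowed elongation rates;
    ``prop='fluor'`` differences per-frame concentrations.  The sign order
    is fixed per pair (left minus right).  Missing data propagates as NaN.
    """
    if prop == "alpha":
        trace_fn = lambda lin: lineage_alpha_trace(lin, window_min)
    elif prop == "fluor":
        trace_fn = lambda lin: _frame_trace(lin, "fluor")
    else:
        raise ValueError("prop must be 'alpha' or 'fluor'")
    if ensemble.n == 0:
        return DeltaSeries(np.zeros(1), np.full((0, 1), np.nan), prop,
                           ensemble.pair_type)
    dt = _infer_dt_ensemble(ensemble)
    grid, left, right = _rel_matrix(ensemble, trace_fn, dt, t_max)
    return DeltaSeries(grid, left - right, prop, ensemble.pair_type)


def saturation_metrics(
    grid: np.ndarray,
    values: np.ndarray,
    plateau_frac: float = 0.25,
    band: float = 0.10,
) -> tuple[float, float]:
    """Plateau value and time of entry into the saturation band.

    The plateau is the mean of the final ``plateau_frac`` of defined grid
    points; the saturation time is the earliest grid point from which the
    series stays within ``+-band`` of the plateau.
    """
    ok = np.flatnonzero(np.isfinite(values))
    if len(ok) == 0:
        return float("nan"), float("nan")
    tail = ok[int(math.floor(len(ok) * (1.0 - plateau_frac))):]
    sat = float(np.mean(values[tail]))
    if sat == 0.0:
        return sat, float(grid[ok[0]])
    inside = np.abs(values[ok] - sat) <= band * abs(sat)
    # earliest index from which every later defined point is inside the band
    stays = np.flip(np.logical_and.accumulate(np.flip(inside)))
    first = ok[np.argmax(stays)] if stays.any() else ok[-1]
    return sat, float(grid[first])


def variance_series(
    deltas: DeltaSeries,
    smooth_frames: int = 3,
    min_pairs: int = 3,
    plateau_frac: float = 0.25,
    band: float = 0.10,
) -> VarianceSeries:
    """Across-pair variance of a difference series with smoothing.

    The variance (population, 1/n) of delta_y over pairs is computed per
    grid point (NaN where fewer than ``min_pairs`` pairs contribute), then
    boxcar-averaged over ``smooth_frames`` consecutive frames.  Plateau
    metrics are computed on the smoothed series.
    """
    d = deltas.deltas
    counts = np.sum(~np.isnan(d), axis=0)
    raw = np.full(d.shape[1], np.nan)
    ok_cols = np.flatnonzero(counts > 0)
    with np.errstate(invalid="ignore"):
        raw[ok_cols] = np.nanvar(d[:, ok_cols], axis=0, ddof=0)
    raw = np.where(counts >= min_pairs, raw, np.nan)
    if smooth_frames > 1:
        sm = pd.Series(raw).rolling(smooth_frames, center=True, min_periods=1
                                    ).mean().to_numpy()
        sm = np.where(np.isfinite(raw) | np.isfinite(sm), sm, np.nan)
    else:
        sm = raw.copy()
    sat, sat_t = saturation_metrics(deltas.grid_min, sm, plateau_frac, band)
    return VarianceSeries(deltas.grid_min, sm, raw, counts, smooth_frames, sat, sat_t)


def variance_by_generation(
    ensemble: PairEnsemble,
    prop: str = "T",
    g_max: int = 10,
    min_pairs: int = 3,
    plateau_frac: float = 0.25,
    band: float = 0.10,
) -> VarianceSeries:
    """Across-pair variance of per-generation differences y1_g - y2_g."""
    grid = np.arange(1, g_max + 1, dtype=float)
    raw = np.full(g_max, np.nan)
    counts = np.zeros(g_max, dtype=int)
    for g in range(1, g_max + 1):
        x, y = _pair_values_at_g(ensemble, prop, g)
        counts[g - 1] = len(x)
        if len(x) >= min_pairs:
            raw[g - 1] = float(np.var(x - y))
    sat, sat_t = saturation_metrics(grid, raw, plateau_frac, band)
    return VarianceSeries(grid, raw.copy(), raw, counts, 1, sat, sat_t)


# ---------------------------------------------------------------------------
# fits and summaries
# ---------------------------------------------------------------------------


def fit_exponential(
    grid: np.ndarray,
    values: np.ndarray,
    x_max: float | None = None,
) -> ExponentialFit:
    """Unweighted nonlinear least squares of A exp(-lambda x), lambda >= 0.

    ``half_life = ln 2 / lambda``; a rate below 1e-6 is reported as
    non-decaying (infinite half-life).  Requires at least 4 finite points.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values) & np.isfinite(grid)
    if x_max is not None:
        mask &= grid <= x_max
    x, y = grid[mask], values[mask]
    if len(x) < 4:
        raise FitError(f"need at least 4 points to fit, got {len(x)}")
    # global 1-D scan over the decay rate: for fixed lambda the optimal
    # amplitude is closed-form, so the SSE landscape (which can carry two
    # local minima for plateau-like series) is scanned exhaustively before
    # a local polish
    span = max(x.max() - x.min(), 1.0)
    lam_grid = np.concatenate([[0.0], np.geomspace(1e-4, 50.0 / span, 600)])
    E = np.exp(-np.outer(lam_grid, x))
    denom = (E * E).sum(axis=1)
    A_grid = (E * y).sum(axis=1) / denom
    sse = ((A_grid[:, None] * E - y) ** 2).sum(axis=1)
    k = int(np.argmin(sse))
    p0 = (float(A_grid[k]), float(lam_grid[k]))
    try:
        popt, _ = curve_fit(
            lambda g, A, lam: A * np.exp(-lam * g), x, y,
            p0=p0, bounds=([-np.inf, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
        A, lam = float(popt[0]), float(popt[1])
        if np.sum((A * np.exp(-lam * x) - y) ** 2) > sse[k]:
            A, lam = p0
    except (RuntimeError, ValueError):
        A, lam = p0
    if not np.isfinite(A) or not np.isfinite(lam):
        raise FitError("exponential fit did not converge",
                       residuals=y - p0[0] * np.exp(-p0[1] * x))
    resid = y - A * np.exp(-lam * x)
    half = NON_DECAYING if lam < _LAMBDA_FLOOR else math.log(2.0) / lam
    return ExponentialFit(A, lam, half, len(x), float(np.sqrt(np.mean(resid ** 2))))


def fit_series(series: CorrelationSeries, x_max: float | None = None) -> ExponentialFit:
    """Fit a correlation series over its full grid, origin included.

    The origin point (value 1 at the alignment division) anchors the fit:
    a pair correlation that relaxes from 1 to a residual shared-environment
    plateau is summarised by the decay rate of that relaxation, which is
    what the memory half-life reports.
    """
    return fit_exponential(series.grid, series.values, x_max=x_max)


def pair_rate_difference_summary(
    sc: PairEnsemble,
    rp: PairEnsemble,
    min_cycles: int = 5,
) -> PairDifferenceSummary:
    """Spread of per-pair average growth-rate differences, SC versus RP.

    For each pair with at least ``min_cycles`` common full cycles, the
    statistic is |mean alpha_cycle(left) - mean alpha_cycle(right)| over
    the common generations.  The SD of these samples is reported per pair
    type together with their ratio sd_sc / sd_rp.
    """
    def _samples(ens: PairEnsemble) -> np.ndarray:
        out = []
        for p in ens.pairs:
            G = min(len(p.left.cycles), len(p.right.cycles))
            if G < min_cycles:
                continue
            a = np.mean([c.alpha_cycle for c in p.left.cycles[:G]])
            b = np.mean([c.alpha_cycle for c in p.right.cycles[:G]])
            out.append(abs(a - b))
        return np.array(out)

    s_sc, s_rp = _samples(sc), _samples(rp)
    if len(s_sc) == 0 or len(s_rp) == 0:
        raise ValueError("all pairs excluded: fewer than min_cycles common cycles")
    return PairDifferenceSummary(s_sc, s_rp, float(np.std(s_sc)), float(np.std(s_rp)))
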