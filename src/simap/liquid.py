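"""Plate-reader growth assays: calibration, exponential fits, liquid LoF.

Absorbance at 600 nm is not linear in cell number at high density, so the
reader is calibrated with serial dilutions against a cubic

    y = a*A600^3 + b*A600^2 + c*A600 + d

where y is the relative number of cells.  Calibrated curves are normalized
to their initial reading, averaged over technical replicates, and fitted to
y = a*exp(k*x) over the log-phase window (the first 6 h after dilution);
the rate constant k (per hour) measures growth rate.

The liquid loss-of-function score of a variant is the linear rescaling of
its rate constant between the wt control and the empty-vector control from
the same microtitre plate:

    lof = (k_var - k_wt) / (k_vec - k_wt)

so wt-like variants score ~0, complete LoF variants ~1, and gain-of-function
variants (growing *slower* than wt because the overexpressed gene is more
active) score negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, DegenerateSentinelError, SchemaError

CURVE_COLUMNS = ["well_id", "variant_id", "time_min", "a600"]


# ---------------------------------------------------------------------------
# cubic calibration

def evaluate_cubic(coeffs: tuple[float, float, float, float], x) -> np.ndarray:
    a, b, c, d = coeffs
    x = np.asarray(x, dtype=float)
    return ((a * x + b) * x + c) * x + d


def cubic_is_monotone(coeffs, lo: float, hi: float) -> bool:
    """True if the cubic is strictly increasing on [lo, hi]."""
    a, b, c, _ = coeffs
    # derivative 3a x^2 + 2b x + c: check endpoints and interior vertex
    candidates = [lo, hi]
    if a != 0:
        vertex = -b / (3.0 * a)
        if lo < vertex < hi:
            candidates.append(vertex)
    deriv = [3 * a * x * x + 2 * b * x + c for x in candidates]
    return min(deriv) > 0


def invert_cubic(coeffs, y, lo: float = 0.0, hi: float | None = None) -> np.ndarray:
    """Invert y = cubic(x) on its monotone range by bracketed root finding.

    The upper bracket is expanded (doubling) until it covers the largest
    requested y; monotonicity is then verified on the final range.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if hi is None:
        hi = max(1.0, lo + 1.0)
        if not cubic_is_monotone(coeffs, lo, hi):
            raise ConfigurationError(
                f"calibration polynomial not strictly increasing on [{lo}, {hi}]")
        y_max = float(np.max(y))
        while evaluate_cubic(coeffs, hi) < y_max:
            hi *= 2.0
            if hi > 1e9:
                raise ConfigurationError("calibration polynomial never reaches requested y")
    if not cubic_is_monotone(coeffs, lo, hi):
        raise ConfigurationError(
            f"calibration polynomial not strictly increasing on [{lo}, {hi}]")
    y_lo = evaluate_cubic(coeffs, lo)
    if np.any(y < y_lo - 1e-12):
        raise ConfigurationError(f"requested y below calibration range (min {y_lo})")
    out = np.empty_like(y)
    for i, yi in enumerate(y):
        if yi <= y_lo:
            out[i] = lo
        else:
            out[i] = optimize.brentq(
                lambda x: evaluate_cubic(coeffs, x) - yi, lo, hi,
                xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return out


@dataclass(frozen=True)
class CalibrationModel:
    """Cubic absorbance-to-cell-number calibration and its validity range."""

    coeffs: tuple[float, float, float, float]
    valid_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not cubic_is_monotone(self.coeffs, lo, hi):
            raise ConfigurationError(
                f"calibration polynomial not monotone on [{lo}, {hi}]; "
                "restrict the range")


def fit_calibration(dilution_table: pd.DataFrame) -> CalibrationModel:
    """Least-squares cubic fit of relative cell number against A600.

    Expects columns ``a600`` and ``relative_cells`` with at least 6 points
    spanning the working range.
    """
    for col in ("a600", "relative_cells"):
        if col not in dilution_table.columns:
            raise SchemaError(f"dilution table missing column {col!r}")
    x = np.asarray(dilution_table["a600"], dtype=float)
    y = np.asarray(dilution_table["relative_cells"], dtype=float)
    if len(x) < 6:
        raise ConfigurationError(f"need >= 6 calibration points, got {len(x)}")
    coeffs = tuple(np.polyfit(x, y, 3))
    return CalibrationModel(coeffs=coeffs, valid_range=(float(x.min()), float(x.max())))


def apply_calibration(model: CalibrationModel, a600_values) -> np.ndarray:
    """Convert A600 readings to relative cell numbers (elementwise cubic).

    Values outside the calibration's valid range are clipped to it; the
    number of clipped values is reported as a warning.
    """
    x = np.asarray(a600_values, dtype=float)
    lo, hi = model.valid_range
    n_clip = int(np.count_nonzero((x < lo) | (x > hi)))
    if n_clip:
        warnings.warn(f"{n_clip} A600 value(s) outside calibration range "
                      f"[{lo:.4g}, {hi:.4g}]; clipped", stacklevel=2)
        x = np.clip(x, lo, hi)
    return evaluate_cubic(model.coeffs, x)


# ---------------------------------------------------------------------------
# growth curves

@dataclass(frozen=True)
class GrowthFit:
    """Exponential fit y = a*exp(k*x) over a log-phase window (x in hours)."""

    a: float
    k: float
    window: tuple[float, float]
    rss: float
    n_points: int
    converged: bool = True


def validate_curves(curves: pd.DataFrame, source: str = "<curves>") -> pd.DataFrame:
    missing = [c for c in CURVE_COLUMNS if c not in curves.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {missing}")
    return curves


def mean_normalized_curve(curves: pd.DataFrame, value_col: str = "y",
                          min_replicates: int = 4) -> pd.DataFrame:
    """Average technical replicates after normalizing each to its t=0 reading.

    ``curves`` is long-format with one well per replicate and a shared time
    grid.  Replicates with a zero (or non-positive) initial reading cannot be
    normalized and are dropped with a warning; fewer than ``min_replicates``
    survivors is an error.
    """
    if value_col not in curves.columns:
        raise SchemaError(f"curves missing value column {value_col!r}")
    wide = curves.pivot_table(index="time_min", columns="well_id", values=value_col)
    if wide.isna().any().any():
        raise SchemaError("replicate wells do not share an identical time grid")
    keep = []
    for well in wide.columns:
        y0 = wide[well].iloc[0]
        if not np.isfinite(y0) or y0 <= 0:
            warnings.warn(f"well {well!r} dropped: zero initial reading", stacklevel=2)
            continue
        keep.append(well)
    if len(keep) < min_replicates:
        raise SchemaError(
            f"only {len(keep)} usable replicate(s); need >= {min_replicates}")
    norm = wide[keep] / wide[keep].iloc[0]
    return pd.DataFrame({"time_min": wide.index.to_numpy(dtype=float),
                         "y": norm.mean(axis=1).to_numpy()})


def fit_exponential(times_min, values, window_h: tuple[float, float] = (0.0, 6.0)) -> GrowthFit:
    """Nonlinear least-squares fit of y = a*exp(k*x) on the log-phase window.

    x is in hours (k is per hour) regardless of the minute-based input grid.
    Initialized from the log-linear regression of ln(y) on x; if the
    nonlinear fit fails to converge the log-linear estimate is returned with
    ``converged=False``.
    """
    t = np.asarray(times_min, dtype=float) / 60.0
    y = np.asarray(values, dtype=float)
    t0, t1 = window_h
    mask = (t >= t0) & (t <= t1)
    t, y = t[mask], y[mask]
    if len(t) < 10:
        raise SchemaError(f"only {len(t)} points in window {window_h}; need >= 10")
    if np.any(y <= 0):
        raise SchemaError("non-positive readings inside the fit window")
    slope, intercept = np.polyfit(t, np.log(y), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    if np.allclose(y, y[0]):
        return GrowthFit(a=float(y[0]), k=0.0, window=window_h, rss=0.0, n_points=len(t))
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, k: a * np.exp(k * x), t, y, p0=p0, maxfev=10000)
        a_hat, k_hat = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        a_hat, k_hat = p0
        converged = False
    rss = float(np.sum((y - a_hat * np.exp(k_hat * t)) ** 2))
    return GrowthFit(a=a_hat, k=k_hat, window=window_h, rss=rss,
                     n_points=len(t), converged=converged)


# ---------------------------------------------------------------------------
# liquid LoF and gain-of-function

@dataclass(frozen=True)
class RateTriple:
    """Rate constants (per hour) for variant, wt and vector from one plate."""

    k_var: float
    k_wt: float
    k_vec: float


def lof_score_liquid(rates: RateTriple, tol: float = 1e-6) -> float:
    """lof = (k_var - k_wt) / (k_vec - k_wt); 0 at wt, 1 at vector."""
    denom = rates.k_vec - rates.k_wt
    if abs(denom) < tol:
        raise DegenerateSentinelError(
            f"|k_vec - k_wt| = {abs(denom):.3g} below tolerance {tol}; "
            "sentinel has no dynamic range in liquid")
    return (rates.k_var - rates.k_wt) / denom


@dataclass(frozen=True)
class GofResult:
    p_value: float
    gof: bool
    mean_k_var: float
    mean_k_wt: float


def gof_test(k_variant_wells, k_wt_wells, alpha: float = 0.05) -> GofResult:
    """Per-well rate comparison declaring gain of function.

    Two-tailed unpaired t-test on per-well rate constants; GoF is declared
    when the variant grows slower than wt on average (more gene activity,
    stronger growth defect) and the difference is significant.
    """
    kv = np.asarray(k_variant_wells, dtype=float)
    kw = np.asarray(k_wt_wells, dtype=float)
    if len(kv) < 3 or len(kw) < 3:
        raise SchemaError("need >= 3 per-well rate estimates on each side")
    if np.allclose(kv, kv[0]) and np.allclose(kw, kw[0]):
        p = 1.0 if np.isclose(kv[0], kw[0]) else 0.0
    else:
        p = float(stats.ttest_ind(kv, kw, equal_var=True).pvalue)
    return GofResult(p_value=p, gof=bool(kv.mean() < kw.mean() and p < alpha),
                     mean_k_var=float(kv.mean()), mean_k_wt=float(kw.mean()))
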