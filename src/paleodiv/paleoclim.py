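"""Palaeo-temperature proxy processing and rate-climate correlation.

The benthic delta-18O record rises as global climate cools, so the series
is negated to form a warmth-increasing temperature proxy: a correlation
of -1 then reads "speciation rate increases with cooler temperatures"
and +1 "with warmer temperatures".  The record is smoothed with a
running mean, linearly interpolated onto the 0.1 Myr rate grid, and
correlated with every posterior speciation-rate curve, once with
Pearson's r and once with the detrended cross-correlation coefficient
rho_DCCA(s), which is robust to the non-stationarity and short-lag
autocorrelation both series carry.  The per-curve coefficients are then
summarized with a one-sample t-test of the mean against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IsotopeSeries",
    "ProxySeries",
    "CorrelationDistribution",
    "UndefinedCorrelationError",
    "load_isotope_series",
    "tukey_smooth",
    "resample_to_grid",
    "pearson_r",
    "dcca_rho",
    "correlate_posterior",
]

GRID_STEP = 0.1  # Myr


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (zero variance / zero detrended fluctuation)."""


@dataclass
class IsotopeSeries:
    """(age Ma, value) pairs with strictly increasing ages."""

    age: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        self.age = np.asarray(self.age, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.age.shape != self.value.shape or self.age.ndim != 1:
            raise ValueError("age and value must be equal-length 1-D arrays")
        if np.any(np.diff(self.age) <= 0):
            raise ValueError("ages must be strictly increasing")

    def __len__(self):
        return len(self.age)


@dataclass
class ProxySeries:
    """Temperature proxy on a uniform age grid (higher = warmer)."""

    age: np.ndarray  # ascending, uniform spacing GRID_STEP
    value: np.ndarray

    def __post_init__(self):
        self.age = np.asarray(self.age, dtype=float)
        self.value = np.asarray(self.value, dtype=float)


@dataclass
class CorrelationDistribution:
    """Per-posterior-sample coefficients with their t-test summary."""

    coefficients: np.ndarray
    method: str  # "pearson" | "dcca(s=<box>)"
    mean: float
    se: float | None
    t: float | None
    p: float | None
    note: str = ""
    n_degenerate: int = 0  # curves with zero variance (no defined coefficient)


def load_isotope_series(path: str) -> IsotopeSeries:
    """Read a two-column CSV (age Ma, value); sort, deduplicate, validate.

    Malformed rows are dropped with a warning naming the line number; a
    header line is tolerated.  Fewer than 3 valid rows is an error.
    """
    ages, values = [], []
    bad: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p for p in line.replace("\t", ",").split(",") if p != ""]
            try:
                a, v = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                if lineno == 1:
                    continue  # header
                bad.append(lineno)
                continue
            ages.append(a)
            values.append(v)
    if bad:
        warnings.warn(f"dropped malformed rows at lines {bad}")
    if len(ages) < 3:
        raise ValueError(f"need >= 3 valid rows, got {len(ages)}")
    age = np.asarray(ages)
    val = np.asarray(values)
    order = np.argsort(age, kind="stable")
    age, val = age[order], val[order]
    keep = np.concatenate([[True], np.diff(age) > 0])
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} duplicate-age rows")
    return IsotopeSeries(age[keep], val[keep])


def tukey_smooth(
    series: IsotopeSeries, window: int = 5, method: str = "mean"
) -> IsotopeSeries:
    """Centered running mean (or median) over ``window`` points.

    ``window`` must be odd; at the series ends the window truncates to
    the available points.  Ages are unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    h = window // 2
    n = len(series)
    out = np.empty(n)
    fn = np.mean if method == "mean" else np.median
    for i in range(n):
        out[i] = fn(series.value[max(0, i - h): min(n, i + h + 1)])
    return IsotopeSeries(series.age.copy(), out)


def resample_to_grid(
    series: IsotopeSeries,
    step: float = GRID_STEP,
    span: tuple[float, float] | None = None,
    negate: bool = True,
) -> ProxySeries:
    """Linear interpolation onto a uniform age grid; no extrapolation.

    ``span`` is (youngest, oldest) in Ma and must lie inside the data
    range.  With ``negate`` (default) the values are sign-flipped into a
    warmth-increasing temperature proxy.
    """
    lo_data, hi_data = float(series.age[0]), float(series.age[-1])
    if span is None:
        lo = np.ceil(lo_data / step - 1e-9) * step
        hi = np.floor(hi_data / step + 1e-9) * step
    else:
        lo, hi = float(span[0]), float(span[1])
    if lo < lo_data - 1e-9 or hi > hi_data + 1e-9:
        raise ValueError(
            f"span [{lo}, {hi}] extends beyond data [{lo_data}, {hi_data}]; "
            f"overhang {max(0.0, lo_data - lo):.4g} / {max(0.0, hi - hi_data):.4g} Myr"
        )
    grid = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    vals = np.interp(grid, series.age, series.value)
    if negate:
        vals = -vals
    return ProxySeries(grid, vals)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; zero variance is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D arrays of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in input")
    with warnings.catch_warnings():
        # near-constant inputs are handled via the finiteness check below
        warnings.simplefilter("ignore")
        r = float(stats.pearsonr(x, y).statistic)
    if not np.isfinite(r):
        raise UndefinedCorrelationError("correlation undefined for input")
    return r


def dcca_rho(x: np.ndarray, y: np.ndarray, box_size: int) -> float:
    """Detrended cross-correlation coefficient rho_DCCA at scale ``box_size``.

    Both series are integrated into mean-centered profiles; every
    overlapping window of ``box_size + 1`` profile points is linearly
    detrended; the coefficient is the mean residual cross-product over
    windows normalized by the two detrended-fluctuation amplitudes, and
    is guaranteed to lie in [-1, 1] (Cauchy-Schwarz).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need equal-length 1-D series")
    n = len(x)
    s = int(box_size)
    if not (4 <= s <= n // 2) or n < s + 2:
        raise ValueError(f"box size {s} out of range [4, {n // 2}] for N={n}")

    px = np.cumsum(x - x.mean())
    py = np.cumsum(y - y.mean())

    # all windows of s+1 consecutive profile points
    wx = np.lib.stride_tricks.sliding_window_view(px, s + 1)
    wy = np.lib.stride_tricks.sliding_window_view(py, s + 1)

    # least-squares linear detrend within each window: residual = w - P w
    t = np.arange(s + 1, dtype=float)
    a = np.column_stack([np.ones_like(t), t])
    proj = a @ np.linalg.inv(a.T @ a) @ a.T
    resid = np.eye(s + 1) - proj
    rx = wx @ resid.T
    ry = wy @ resid.T

    f2_xy = np.mean(np.mean(rx * ry, axis=1))
    f2_xx = np.mean(np.mean(rx * rx, axis=1))
    f2_yy = np.mean(np.mean(ry * ry, axis=1))
    if f2_xx <= 0 or f2_yy <= 0:
        raise UndefinedCorrelationError("zero detrended fluctuation")
    return float(f2_xy / np.sqrt(f2_xx * f2_yy))


def _overlap(grid_a: np.ndarray, grid_b: np.ndarray, step: float):
    lo = max(grid_a[0], grid_b[0])
    hi = min(grid_a[-1], grid_b[-1])
    if hi - lo < 2 * step:
        raise ValueError("rate and proxy grids barely overlap")
    ia = slice(int(round((lo - grid_a[0]) / step)),
               int(round((hi - grid_a[0]) / step)) + 1)
    ib = slice(int(round((lo - grid_b[0]) / step)),
               int(round((hi - grid_b[0]) / step)) + 1)
    return ia, ib


def correlate_posterior(
    curves,
    proxy: ProxySeries,
    method: str = "pearson",
    box_size: int | None = None,
    step: float = GRID_STEP,
) -> CorrelationDistribution:
    """One coefficient per posterior rate curve, plus a t-test of the mean.

    ``curves`` is a list of objects with ``age``/``rate`` arrays (see
    :class:`paleodiv.shiftbd.RateCurve`) or a 2-D matrix paired with the
    proxy grid.  Coefficients are computed on the overlap of the rate
    grid and the proxy grid; the reported p-value is a two-sided
    one-sample t-test of the coefficient mean against zero.  Posterior
    draws are correlated, so the effective sample size is smaller than
    the curve count; the note field records this caveat.
    """
    if method not in ("pearson", "dcca"):
        raise ValueError("method must be 'pearson' or 'dcca'")
    if not len(curves):
        raise ValueError("no rate curves given")

    coeffs = []
    n_degen = 0
    for curve in curves:
        age = np.asarray(curve.age, dtype=float)
        rate = np.asarray(curve.rate, dtype=float)
        ia, ib = _overlap(age, proxy.age, step)
        r, p = rate[ia], proxy.value[ib]
        try:
            if method == "pearson":
                coeffs.append(pearson_r(r, p))
            else:
                s = box_size if box_size is not None else max(4, len(r) // 4)
                coeffs.append(dcca_rho(r, p, s))
        except UndefinedCorrelationError:
            # constant rate curve (e.g. a zero-shift posterior draw):
            # no correlation is defined, so the draw contributes nothing
            n_degen += 1
    if not coeffs:
        raise UndefinedCorrelationError(
            "every rate curve is constant over the correlation span"
        )
    coeffs = np.asarray(coeffs)
    tag = "pearson" if method == "pearson" else f"dcca(s={box_size if box_size else 'N/4'})"

    mean = float(coeffs.mean())
    if len(coeffs) < 2 or np.std(coeffs, ddof=1) == 0:
        return CorrelationDistribution(
            coeffs, tag, mean, None, None, None,
            note="degenerate coefficient set: t-test undefined (zero variance)",
            n_degenerate=n_degen,
        )
    res = stats.ttest_1samp(coeffs, 0.0)
    se = float(np.std(coeffs, ddof=1) / np.sqrt(len(coeffs)))
    return CorrelationDistribution(
        coeffs, tag, mean, se, float(res.statistic), float(res.pvalue),
        note=(
            "posterior draws are autocorrelated; the t-test treats them as "
            "independent, so the effective sample size is overstated"
        ),
        n_degenerate=n_degen,
    )
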