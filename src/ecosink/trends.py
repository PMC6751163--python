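"""LAI trend statistics, accumulated-sink curves, and disturbance-pixel
exclusion accounting.

Per-pixel trends are ordinary least squares on the year index with a
two-tailed t-test on the slope; area fractions ("x% of the land surface
shows an increasing trend") are cos-latitude area weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ecosink.units import grams_to_petagrams


@dataclass
class TrendResult:
    """Per-pixel slopes and p-values with area-weighted summary fractions."""

    slope: np.ndarray  # units yr-1
    p_value: np.ndarray
    significant: np.ndarray  # p < alpha
    frac_positive: float  # area fraction with slope > 0
    frac_positive_significant: float  # of the positive-trend area
    alpha: float = 0.05


@dataclass
class DisturbanceMask:
    """Fractional change in short-vegetation and tree cover per pixel with
    exclusion flags at the >20% and >30% thresholds (the 30% set is a
    subset of the 20% set by construction)."""

    sv_change: np.ndarray  # fraction in [0, 1]
    tc_change: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.sv_change, self.tc_change):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError("cover changes must lie in [0, 1]")

    def excluded(self, threshold: float) -> np.ndarray:
        if not np.isclose(threshold, 0.2) and not np.isclose(threshold, 0.3):
            raise ValueError("threshold must be 0.2 or 0.3")
        return (self.sv_change > threshold) | (self.tc_change > threshold)


def growing_season_mean(daily_lai: np.ndarray, amplitude_frac: float = 0.2):
    """Annual growing-season mean LAI per pixel.

    The season is defined per pixel from its daily climatology: days with
    climatological LAI >= min + ``amplitude_frac`` * (max - min). Evergreen
    pixels (zero amplitude) use the full year. Pixels with an all-zero
    climatology have no season and return NaN.

    Parameters
    ----------
    daily_lai : (n_years, 365, n_pix)

    Returns
    -------
    (n_years, n_pix) annual means.
    """
    daily = np.asarray(daily_lai, dtype=float)
    clim = daily.mean(axis=0)  # (365, n_pix)
    lo = clim.min(axis=0)
    hi = clim.max(axis=0)
    thresh = lo + amplitude_frac * (hi - lo)
    in_season = clim >= thresh[None, :]  # evergreen: always true
    n_days = in_season.sum(axis=0)
    dead = hi <= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (np.where(in_season[None], daily, 0.0).sum(axis=1)
               / np.maximum(n_days, 1)[None, :])
    out[:, dead] = np.nan
    return out


def linear_trend(series: np.ndarray, method: str = "ols"):
    """Per-series trend slope and two-tailed p-value.

    ``series`` is (n_years,) or (n_years, n_pix); requires n >= 3. The
    default estimator is OLS on the year index with a t-test on the slope;
    ``method="theil-sen"`` gives the rank-based alternative (Theil--Sen
    slope with a Mann--Kendall-equivalent Kendall-tau p-value). A
    zero-variance series yields slope 0 with p = 1.
    """
    if method == "theil-sen":
        return _rank_trend(series)
    if method != "ols":
        raise ValueError("method must be 'ols' or 'theil-sen'")
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    y = np.atleast_2d(y.T).T  # (n, m)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 years for a trend")
    x = np.arange(n, dtype=float)
    xc = x - x.mean()
    sxx = (xc**2).sum()
    yc = y - y.mean(axis=0, keepdims=True)
    slope = (xc[:, None] * yc).sum(axis=0) / sxx
    resid = yc - slope[None, :] * xc[:, None]
    sse = (resid**2).sum(axis=0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / dof / sxx)
        t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    degenerate = sse <= 0
    # an exact line: p -> 0 unless the slope is also 0 (constant series)
    exact = degenerate & (slope != 0)
    p = np.where(exact, 0.0, p)
    const = degenerate & (slope == 0)
    slope = np.where(const, 0.0, slope)
    p = np.where(const, 1.0, p)
    if squeeze:
        return float(slope[0]), float(p[0])
    return slope, p


def _rank_trend(series: np.ndarray):
    """Theil--Sen slope with Kendall-tau two-tailed p-value, per series."""
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    y2 = np.atleast_2d(y.T)
    x = np.arange(y2.shape[1], dtype=float)
    slopes = np.empty(y2.shape[0])
    ps = np.empty(y2.shape[0])
    for i, row in enumerate(y2):
        if np.ptp(row) == 0:
            slopes[i], ps[i] = 0.0, 1.0
            continue
        slopes[i] = stats.theilslopes(row, x).slope
        ps[i] = stats.kendalltau(x, row).pvalue
    if squeeze:
        return float(slopes[0]), float(ps[0])
    return slopes, ps


def trend_map(annual_values: np.ndarray, areas: np.ndarray,
              alpha: float = 0.05, method: str = "ols") -> TrendResult:
    """Per-pixel trends of annual values with area-weighted summary
    fractions: the fraction of the surface with a positive trend, and the
    fraction of that positive-trend area significant at ``alpha``
    (two-tailed). ``method`` selects the estimator (default OLS)."""
    slope, p = linear_trend(annual_values, method=method)
    areas = np.asarray(areas, dtype=float)
    valid = np.isfinite(slope)
    pos = valid & (slope > 0)
    area_valid = (areas * valid).sum()
    frac_pos = float((areas * pos).sum() / area_valid) if area_valid else np.nan
    sig = p < alpha
    area_pos = (areas * pos).sum()
    frac_pos_sig = float((areas * (pos & sig)).sum() / area_pos) \
        if area_pos else np.nan
    return TrendResult(slope=slope, p_value=p, significant=sig,
                       frac_positive=frac_pos,
                       frac_positive_significant=frac_pos_sig, alpha=alpha)


def accumulate_nep(annual_nep: np.ndarray, areas: np.ndarray,
                   pixel_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Global annual and cumulative NEP series in Pg C.

    ``annual_nep`` is (n_years, n_pix) in g C m-2 yr-1; ``areas`` in m2.
    """
    nep = np.asarray(annual_nep, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if pixel_mask is not None:
        areas = areas * np.asarray(pixel_mask, dtype=bool)
    annual_pg = grams_to_petagrams((nep * areas[None, :]).sum(axis=1))
    return pd.DataFrame({"annual_pg_c": annual_pg,
                         "cumulative_pg_c": np.cumsum(annual_pg)})


def exclude_disturbed(annual_nep: np.ndarray, areas: np.ndarray,
                      mask: DisturbanceMask, threshold: float):
    """Accumulated-sink curve excluding disturbance-flagged pixels.

    Returns ``(curve, percent_reduction)``: the cumulative series over
    unflagged pixels and the relative reduction (in percent) of the final
    accumulated NEP versus the full accumulation.
    """
    flagged = mask.excluded(threshold)
    full = accumulate_nep(annual_nep, areas)
    part = accumulate_nep(annual_nep, areas, pixel_mask=~flagged)
    total = full["cumulative_pg_c"].iloc[-1]
    reduction = 100.0 * (total - part["cumulative_pg_c"].iloc[-1]) / total \
        if total else np.nan
    return part, float(reduction)
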