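"""Thermal-regime metrics from monthly SST series.

A series is a pandas Series of monthly temperatures (degC) with a monthly
PeriodIndex. Three summary metrics characterize a regime: the mean, the
coefficient of variation (sd / mean of the raw monthly values), and the
spectral exponent beta — the ordinary-least-squares slope of log10 raw
periodogram density on log10 frequency. More negative beta means variance
concentrated in slow ("reddened") fluctuations. No tapering, smoothing or
deseasonalization is applied by default; the annual cycle stays in the
spectrum (a ``deseasonalize`` flag exists for sensitivity checks).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["read_sst", "write_sst", "sst_summary", "spectral_exponent",
           "validate_series"]


def validate_series(series: pd.Series) -> pd.Series:
    """Require a gap-free, strictly increasing monthly index."""
    if not isinstance(series.index, pd.PeriodIndex):
        raise ValueError("series must carry a monthly PeriodIndex")
    diffs = np.diff(series.index.asi8)
    if len(series) and not np.all(diffs == 1):
        raise ValueError("series has gaps or non-increasing time stamps")
    return series


def read_sst(path) -> pd.Series:
    """Two-column CSV (year-month, degC) -> monthly Series."""
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValueError("SST file must have exactly two columns")
    idx = pd.PeriodIndex(df.iloc[:, 0].astype(str), freq="M")
    series = pd.Series(df.iloc[:, 1].to_numpy(float), index=idx, name="sst")
    return validate_series(series)


def write_sst(path, series: pd.Series) -> None:
    validate_series(series)
    out = pd.DataFrame({"month": series.index.astype(str),
                        "sst": series.to_numpy()})
    out.to_csv(path, index=False)


def sst_summary(series) -> tuple[float, float]:
    """Mean and coefficient of variation of the raw monthly series."""
    x = np.asarray(series, float)
    if x.size < 24:
        raise ValueError("need at least 24 months")
    mean = float(x.mean())
    if mean <= 0:
        warnings.warn("non-positive mean temperature: the coefficient of "
                      "variation is scale-dependent and unreliable",
                      stacklevel=2)
    cv = float(x.std(ddof=1) / mean) if mean != 0 else float("nan")
    return mean, cv


def _remove_monthly_means(x: np.ndarray) -> np.ndarray:
    out = x.copy()
    for m in range(12):
        out[m::12] -= out[m::12].mean()
    return out


def spectral_exponent(series, *, deseasonalize: bool = False,
                      full: bool = False):
    """OLS slope of log10 periodogram density on log10 frequency.

    Uses the raw periodogram |FFT|^2 / n at frequencies k/n for
    k = 1..floor(n/2). Zero ordinates are dropped (with a warning). With
    ``full=True`` returns ``(beta, r_squared, n_dropped)``; a low r-squared
    marks a spectrum dominated by a single line (for example a pure
    sinusoid).
    """
    x = np.asarray(series, float)
    if x.size < 64:
        raise ValueError("need at least 64 months for a spectral fit")
    n = x.size
    x = x - x.mean()
    if deseasonalize:
        x = _remove_monthly_means(x)
    spec = np.fft.rfft(x)
    k = np.arange(1, n // 2 + 1)
    power = np.abs(spec[k]) ** 2 / n
    freqs = k / n
    # ordinates that are zero to numerical precision (exact zeros, or
    # harmonics nulled by deseasonalization) cannot enter a log regression
    keep = power > 1e-12 * np.median(power)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero periodogram ordinates",
                      stacklevel=2)
    lx = np.log10(freqs[keep])
    ly = np.log10(power[keep])
    if lx.size < 3:
        raise ValueError("too few usable periodogram ordinates")
    slope, intercept = np.polyfit(lx, ly, 1)
    fitted = slope * lx + intercept
    ss_res = float(np.sum((ly - fitted) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < 0.1:
        warnings.warn("power-law fit explains <10% of spectral variance; "
                      "spectrum may be dominated by a single line",
                      stacklevel=2)
    beta = float(slope)
    if full:
        return beta, float(r2), n_dropped
    return beta
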