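"""Single-component cosinor fitting with fixed or estimated period.

The fixed-period fit is exact least squares on the basis
{1, cos(2*pi*t/tau), sin(2*pi*t/tau)}; the free-period fit profiles the RSS
over a 0.01-hour grid and refines the minimizer by golden-section search.
The acrophase is reported as the peak time in hours on [0, period), and the
zero-amplitude test is the F(2, n-3) comparison against the mesor-only
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from scrhythm.io import TimeSeries

GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


class RankDeficientBasis(ValueError):
    """The cosine/sine basis is collinear at the requested period."""


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase_hours: float
    period_hours: float
    rss: float
    rss_null: float
    f_stat: float
    df: tuple[int, int]
    pvalue: float
    n: int
    degenerate: bool = False
    profile: np.ndarray | None = field(default=None, repr=False)

    def predict(self, times: np.ndarray) -> np.ndarray:
        return self.mesor + self.amplitude * np.cos(
            2.0 * np.pi * (np.asarray(times) - self.acrophase_hours)
            / self.period_hours
        )


def _design(times: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi / period
    return np.column_stack(
        [np.ones_like(times), np.cos(w * times), np.sin(w * times)]
    )


def fit_cosinor_fixed(series: TimeSeries, period: float) -> CosinorFit:
    """Exact least-squares cosinor at a known period.

    Requires at least 4 points and a basis of full rank (a period equal to
    the sampling interval aliases the cosine onto a constant and raises
    :class:`RankDeficientBasis`).
    """
    t, y = series.times, series.values
    n = len(t)
    if n < 4:
        raise ValueError("cosinor needs at least 4 points")
    if period <= 0:
        raise ValueError("period must be positive")
    if np.all(t == t[0]):
        raise ValueError("times must not all be identical")
    X = _design(t, period)
    if np.linalg.matrix_rank(X, tol=1e-8 * n) < 3:
        raise RankDeficientBasis(
            f"cos/sin basis is rank deficient at period {period}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, bc, bs = beta
    amplitude = float(np.hypot(bc, bs))
    acrophase = float((np.arctan2(bs, bc) * period / (2.0 * np.pi)) % period)
    resid = y - X @ beta
    rss = float(resid @ resid)
    rss_null = float(np.sum((y - y.mean()) ** 2))
    df = (2, n - 3)
    scale = max(rss_null, 1.0)
    if rss_null - rss <= 1e-12 * scale:
        f_stat, pvalue = 0.0, 1.0
    elif rss <= 1e-12 * scale:
        f_stat, pvalue = np.inf, 0.0
    else:
        f_stat = ((rss_null - rss) / 2.0) / (rss / (n - 3))
        pvalue = float(stats.f.sf(f_stat, *df))
    return CosinorFit(
        mesor=float(mesor),
        amplitude=amplitude,
        acrophase_hours=acrophase,
        period_hours=float(period),
        rss=rss,
        rss_null=rss_null,
        f_stat=float(f_stat),
        df=df,
        pvalue=pvalue,
        n=n,
    )


def fit_cosinor_free(
    series: TimeSeries,
    period_lo: float = 20.0,
    period_hi: float = 28.0,
    grid_step: float = 0.01,
    refine_tol: float = 1e-4,
) -> CosinorFit:
    """Free-period cosinor: grid profile of the RSS plus golden-section refine.

    Periods at which the basis is rank deficient are skipped on the grid.
    An all-constant series leaves the period unidentifiable; the fit is
    returned flagged ``degenerate`` at the midpoint period.
    """
    if period_lo >= period_hi:
        raise ValueError("period_lo must be < period_hi")
    if len(series.times) < 5:
        raise ValueError("free-period cosinor needs at least 5 points")
    y = series.values
    if np.all(y == y[0]):
        fit = fit_cosinor_fixed(series, 0.5 * (period_lo + period_hi))
        fit.degenerate = True
        return fit

    periods = np.arange(period_lo, period_hi + grid_step / 2.0, grid_step)
    t = series.times

    def rss_at(tau: float) -> float:
        # direct normal-equations solve; falls back on ill conditioning
        X = _design(t, tau)
        xtx = X.T @ X
        try:
            beta = np.linalg.solve(xtx, X.T @ y)
        except np.linalg.LinAlgError:
            return np.inf
        if np.linalg.cond(xtx) > 1e10:
            return np.inf
        resid = y - X @ beta
        return float(resid @ resid)
    profile = np.array([rss_at(tau) for tau in periods])
    if not np.isfinite(profile).any():
        raise RankDeficientBasis("basis rank deficient on the whole grid")
    best = int(np.argmin(profile))

    lo = periods[max(best - 1, 0)]
    hi = periods[min(best + 1, len(periods) - 1)]
    # golden-section search on [lo, hi]
    a, b = lo, hi
    c = b - GOLDEN * (b - a)
    d = a + GOLDEN * (b - a)
    fc, fd = rss_at(c), rss_at(d)
    while b - a > refine_tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - GOLDEN * (b - a)
            fc = rss_at(c)
        else:
            a, c, fc = c, d, fd
            d = a + GOLDEN * (b - a)
            fd = rss_at(d)
    tau_hat = 0.5 * (a + b)
    if not np.isfinite(rss_at(tau_hat)):
        tau_hat = periods[best]
    fit = fit_cosinor_fixed(series, tau_hat)
    fit.profile = np.column_stack([periods, profile])
    return fit
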