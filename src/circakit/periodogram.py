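"""Chi-squared (Sokolove-Bushell) periodogram for free-running period.

For each candidate period P (an integer number of bins, so folding is
exact) the series is cut into K complete cycles; with column means M_h over
the fold, grand mean M-bar and N = K*P bins used,

    Q_P = K * N * sum_h (M_h - M_bar)^2 / sum_i (x_i - M_bar)^2 .

Under white noise Q_P is approximately chi-square with P-1 degrees of
freedom, which supplies the per-period significance line. The best period
is the candidate maximising Q_P above (minus) its significance line. The
trailing partial cycle is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DegenerateInputError, InvalidArgumentError
from .simulate import ActivityRecording


@dataclass
class PeriodogramResult:
    periods: np.ndarray         # hours
    q_stat: np.ndarray
    significance_line: np.ndarray
    best_period: float
    significant: bool


class ChiSquaredPeriodogram(BaseEstimator):
    """Sokolove-Bushell periodogram as an estimator.

    Parameters
    ----------
    period_min, period_max : float
        Candidate period range in hours (inclusive).
    step_h : float
        Grid step in hours; must be a multiple of the bin width so that
        every candidate period is an integer number of bins.
    alpha_sig : float
        Level of the per-period chi-square significance line.
    bin_minutes : int
        Bin width of the input series.

    Fitted attributes: ``periods_``, ``q_stat_``, ``significance_line_``,
    ``best_period_``, ``significant_``.
    """

    def __init__(self, period_min: float = 20.0, period_max: float = 28.0,
                 step_h: float = 0.1, alpha_sig: float = 0.05,
                 bin_minutes: int = 6):
        self.period_min = period_min
        self.period_max = period_max
        self.step_h = step_h
        self.alpha_sig = alpha_sig
        self.bin_minutes = bin_minutes

    def _grid_bins(self) -> np.ndarray:
        bin_h = self.bin_minutes / 60.0
        step_bins = self.step_h / bin_h
        if abs(step_bins - round(step_bins)) > 1e-9 or round(step_bins) < 1:
            raise InvalidArgumentError(
                "step_h must be a positive multiple of the bin width"
            )
        step_bins = int(round(step_bins))
        lo = int(np.ceil(self.period_min / bin_h - 1e-9))
        hi = int(np.floor(self.period_max / bin_h + 1e-9))
        lo += (-lo) % step_bins if lo % step_bins else 0
        grid = np.arange(lo, hi + 1, step_bins)
        if grid.size == 0:
            raise InvalidArgumentError("empty period grid")
        return grid

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        bin_h = self.bin_minutes / 60.0
        if x.size * bin_h < 2 * self.period_max:
            raise InvalidArgumentError(
                "recording must span at least twice the longest candidate period"
            )
        grand_var = np.sum((x - x.mean()) ** 2)
        if grand_var == 0:
            raise DegenerateInputError("flat series has no periodicity")

        grid = self._grid_bins()
        q = np.empty(grid.size)
        for i, p in enumerate(grid):
            k = x.size // p
            used = x[: k * p]
            mbar = used.mean()
            mh = used.reshape(k, p).mean(axis=0)
            denom = np.sum((used - mbar) ** 2)
            q[i] = k * used.size * np.sum((mh - mbar) ** 2) / denom

        line = stats.chi2.ppf(1.0 - self.alpha_sig, grid - 1)
        best = int(np.argmax(q - line))
        self.periods_ = grid * bin_h
        self.q_stat_ = q
        self.significance_line_ = line
        self.best_period_ = float(self.periods_[best])
        self.significant_ = bool(q[best] > line[best])
        return self

    def result_(self) -> PeriodogramResult:
        return PeriodogramResult(
            periods=self.periods_,
            q_stat=self.q_stat_,
            significance_line=self.significance_line_,
            best_period=self.best_period_,
            significant=self.significant_,
        )


def chi_squared_periodogram(
    rec: ActivityRecording,
    p_min: float = 20.0,
    p_max: float = 28.0,
    alpha_sig: float = 0.05,
    step_h: float = 0.1,
) -> PeriodogramResult:
    """Chi-squared periodogram of a binned activity recording."""
    est = ChiSquaredPeriodogram(
        period_min=p_min,
        period_max=p_max,
        step_h=step_h,
        alpha_sig=alpha_sig,
        bin_minutes=rec.bin_minutes,
    ).fit(rec.counts)
    return est.result_()
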