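"""Single-cosinor rhythmometry and percent-of-daily-mean normalization.

The single cosinor fits, by ordinary least squares,

    y(t) = M + beta*cos(2*pi*t/P) + gamma*sin(2*pi*t/P),

with the period P fixed (24 h for entrained data). The rhythm parameters
follow as amplitude A = sqrt(beta^2 + gamma^2) and acrophase
phi = (P/2pi)*atan2(gamma, beta) mod P — reported here as the peak time in
ZT hours rather than the classical negative-radians convention, because
that is how peripheral-clock phases are plotted. Rhythmicity is the
zero-amplitude test: the 2-df F test of beta = gamma = 0 against the
residual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from . import _circular as circ
from .errors import InvalidArgumentError, SingularFitError
from .simulate import BioluminescenceSeries


@dataclass
class CosinorFit:
    period: float
    mesor: float
    amplitude: float
    acrophase_zt: float
    p_zero_amplitude: float
    residual_ss: float


@dataclass
class GroupAcrophase:
    mean_zt: float
    sem: float
    n_used: int
    n_arrhythmic: int


def percent_of_mean(values) -> np.ndarray:
    """Rescale positive values so that their mean is exactly 100."""
    x = np.asarray(values, dtype=float)
    if x.size == 0 or np.any(x <= 0):
        raise InvalidArgumentError("values must be positive")
    return 100.0 * x / x.mean()


def normalize_to_daily_mean(series: BioluminescenceSeries) -> BioluminescenceSeries:
    """Convert a six-point photon-rate series to percent of its daily mean
    (daily average == 100%)."""
    return BioluminescenceSeries(
        animal_id=series.animal_id,
        organ=series.organ,
        sample_clock_times=series.sample_clock_times,
        photon_rates=series.photon_rates,
        normalized_pct=percent_of_mean(series.photon_rates),
    )


class Cosinor(BaseEstimator, RegressorMixin):
    """Fixed-period single cosinor regression.

    Fitted attributes: ``mesor_``, ``amplitude_``, ``acrophase_zt_``,
    ``p_zero_amplitude_``, ``residual_ss_``, ``coef_`` (beta, gamma).
    """

    def __init__(self, period: float = 24.0):
        self.period = period

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        yv = np.asarray(y, dtype=float).ravel()
        if t.size != yv.size:
            raise InvalidArgumentError("times and values differ in length")
        if np.unique(np.mod(t, self.period)).size < 4:
            raise InvalidArgumentError("need at least 4 distinct time points")
        omega = 2.0 * np.pi / self.period
        design = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
        if np.linalg.matrix_rank(design) < 3:
            raise SingularFitError("cosinor design matrix is rank deficient")

        coef, _, _, _ = np.linalg.lstsq(design, yv, rcond=None)
        mesor, beta, gamma = coef
        resid = yv - design @ coef
        ss_full = float(resid @ resid)
        ss_null = float(np.sum((yv - yv.mean()) ** 2))
        n = t.size

        amplitude = float(np.hypot(beta, gamma))
        acro = float(np.mod(np.arctan2(gamma, beta) / omega, self.period))

        scale = max(ss_null, 1.0)
        if ss_null <= 1e-12 * scale:
            p = 1.0  # constant input: nothing to explain
        elif ss_full <= 1e-12 * ss_null:
            p = 0.0  # rhythm explains essentially all variance
        else:
            f = ((ss_null - ss_full) / 2.0) / (ss_full / (n - 3))
            p = float(stats.f.sf(f, 2, n - 3))

        self.mesor_ = float(mesor)
        self.coef_ = np.array([beta, gamma])
        self.amplitude_ = amplitude
        self.acrophase_zt_ = acro
        self.p_zero_amplitude_ = p
        self.residual_ss_ = ss_full
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).ravel()
        omega = 2.0 * np.pi / self.period
        return self.mesor_ + self.amplitude_ * np.cos(
            omega * (t - self.acrophase_zt_)
        )

    def result_(self) -> CosinorFit:
        return CosinorFit(
            period=self.period,
            mesor=self.mesor_,
            amplitude=self.amplitude_,
            acrophase_zt=self.acrophase_zt_,
            p_zero_amplitude=self.p_zero_amplitude_,
            residual_ss=self.residual_ss_,
        )


def cosinor_fit(times_zt: Sequence[float], values: Sequence[float],
                period: float = 24.0) -> CosinorFit:
    """Least-squares single cosinor at fixed period (see Cosinor)."""
    return Cosinor(period=period).fit(times_zt, values).result_()


def group_acrophase(
    fits: Sequence[CosinorFit],
    include_arrhythmic: bool = True,
    rhythm_alpha: float = 0.05,
) -> GroupAcrophase:
    """Circular mean acrophase of a group of fits with a circular-aware SEM.

    Fits failing the zero-amplitude test at ``rhythm_alpha`` are counted as
    arrhythmic; by default they still enter the mean (matching per-animal
    acrophase plots), or are excluded with ``include_arrhythmic=False``.
    """
    if len(fits) < 2:
        raise InvalidArgumentError("need at least 2 fits for a group summary")
    arr = [f for f in fits if f.p_zero_amplitude >= rhythm_alpha]
    used = fits if include_arrhythmic else [
        f for f in fits if f.p_zero_amplitude < rhythm_alpha
    ]
    if len(used) < 2:
        raise InvalidArgumentError("fewer than 2 rhythmic fits to summarise")
    phases = np.array([f.acrophase_zt for f in used])
    return GroupAcrophase(
        mean_zt=circ.circ_mean(phases),
        sem=circ.circ_sem(phases),
        n_used=len(used),
        n_arrhythmic=len(arr),
    )
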