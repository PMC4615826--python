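"""Reference connectivity and spectral measures: Granger causality and
FFT band power.

These are the linear comparison measures run alongside transfer
entropy: bivariate Granger causality (GC) with the vector-
autoregression order chosen by the Bayesian Information Criterion,
and periodogram band powers in the four classic EEG bands with their
Pearson correlation against the driving-performance index.

GC here is the log residual-variance ratio

    GC(y -> x) = ln( var(eps | own past) / var(eps | own + source past) )

in nats, non-negative up to sampling error; for jointly Gaussian
processes it equals twice the transfer entropy (in nats), which is
exploited as a cross-validation oracle elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "BandDefinition",
    "BANDS",
    "fit_var_order_bic",
    "granger",
    "granger_ftest",
    "band_power",
    "band_powers_table",
    "band_dp_correlation",
]


@dataclass(frozen=True)
class BandDefinition:
    """Inclusive frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 <= self.lo <= self.hi:
            raise ValueError(f"invalid band edges ({self.lo}, {self.hi})")


#: The four analysis bands.  The printed ranges are disjoint: the 4 Hz
#: bin belongs to delta only and the 5 Hz bin to theta only.
BANDS = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 5.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 20.0),
}


def _lag_matrix(series: np.ndarray, p: int, t0: int) -> np.ndarray:
    """Columns series_{t-1} .. series_{t-p} for t in [t0, n)."""
    n = series.size
    return np.column_stack([series[t0 - j: n - j] for j in range(1, p + 1)])


def _ols_rss(design: np.ndarray, target: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    return float(resid @ resid)


def fit_var_order_bic(x, y, p_max: int = 10) -> int:
    """VAR order for the pair (x, y) minimizing the BIC over 1..p_max.

    All candidate orders are scored on the same effective sample
    (observations from ``t = p_max`` on) so their likelihoods are
    comparable.  BIC = ln det(Sigma_ml) + n_params * ln(T) / T.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("series must have equal length")
    if n <= 10 * p_max:
        raise ValueError(f"need length > {10 * p_max} for p_max={p_max}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series: VAR design matrix is singular")
    t_eff = n - p_max
    targets = np.column_stack([x[p_max:], y[p_max:]])
    best_p, best_bic = None, np.inf
    for p in range(1, p_max + 1):
        design = np.column_stack([
            _lag_matrix(x, p, p_max), _lag_matrix(y, p, p_max),
            np.ones(t_eff),
        ])
        coef, *_ = np.linalg.lstsq(design, targets, rcond=None)
        resid = targets - design @ coef
        sigma = resid.T @ resid / t_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise ValueError("singular residual covariance in VAR fit")
        n_params = 2 * (2 * p + 1)
        bic = logdet + n_params * np.log(t_eff) / t_eff
        if bic < best_bic:
            best_p, best_bic = p, bic
    return best_p


def _granger_rss(x: np.ndarray, y: np.ndarray, p: int):
    n = x.size
    if n <= 3 * p + 2:
        raise ValueError("series too short for the requested order")
    target = x[p:]
    own = np.column_stack([_lag_matrix(x, p, p), np.ones(n - p)])
    full = np.column_stack([_lag_matrix(x, p, p), _lag_matrix(y, p, p),
                            np.ones(n - p)])
    return _ols_rss(own, target), _ols_rss(full, target), n - p


def granger(x, y, p: int) -> float:
    """Granger causality y -> x in nats at VAR order ``p``.

    ``x`` is the sink, ``y`` the source.  Returns
    ``ln(RSS_restricted / RSS_full)``; non-negative up to numerical
    tolerance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    rss_r, rss_f, _ = _granger_rss(x, y, p)
    if not np.isfinite(rss_r) or not np.isfinite(rss_f) or rss_f <= 0:
        raise ValueError("non-finite residual variance in Granger fit")
    return float(np.log(rss_r / rss_f))


def granger_ftest(x, y, p: int) -> tuple[float, float, float]:
    """Granger causality with its asymptotic F-test.

    Returns ``(gc_nats, F, p_value)`` where F has (p, T - 2p - 1)
    degrees of freedom under the no-causality null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rss_r, rss_f, t_eff = _granger_rss(x, y, p)
    df2 = t_eff - 2 * p - 1
    if df2 <= 0:
        raise ValueError("not enough observations for the F-test")
    f_stat = ((rss_r - rss_f) / p) / (rss_f / df2)
    p_val = float(_stats.f.sf(f_stat, p, df2))
    return float(np.log(rss_r / rss_f)), float(f_stat), p_val


def band_power(epoch, fs: float, band: BandDefinition) -> float:
    """Periodogram power of one epoch summed over the band's bins.

    A rectangular (no taper) periodogram of the 1-s epoch gives
    integer-Hz bin spacing; bins with ``lo <= f <= hi`` are summed.
    """
    epoch = np.asarray(epoch, dtype=float)
    if band.hi > fs / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist ({fs / 2} Hz)")
    freqs, pxx = _signal.periodogram(epoch, fs=fs, window="boxcar",
                                     detrend=False)
    sel = (freqs >= band.lo - 1e-9) & (freqs <= band.hi + 1e-9)
    return float(pxx[sel].sum())


def band_powers_table(epochs_2d, fs: float, log10: bool = True) -> dict:
    """Per-trial band powers for one channel's trials x samples array.

    Returns ``{band_name: ndarray of per-trial power}``; powers are
    log10-transformed by default (band-power distributions are
    heavily right-skewed, and correlations against DP are computed on
    the log scale unless configured otherwise).
    """
    epochs_2d = np.atleast_2d(np.asarray(epochs_2d, dtype=float))
    out = {}
    for name, band in BANDS.items():
        vals = np.array([band_power(ep, fs, band) for ep in epochs_2d])
        if log10:
            vals = np.log10(np.maximum(vals, 1e-300))
        out[name] = vals
    return out


def band_dp_correlation(band_powers, dps) -> float:
    """Pearson correlation between per-trial band power and DP."""
    bp = np.asarray(band_powers, dtype=float)
    dp = np.asarray(dps, dtype=float)
    if bp.size != dp.size or bp.size < 3:
        raise ValueError("need >= 3 paired finite observations")
    if not (np.all(np.isfinite(bp)) and np.all(np.isfinite(dp))):
        raise ValueError("inputs must be finite")
    if np.ptp(bp) == 0 or np.ptp(dp) == 0:
        raise ValueError("zero variance in band power or DP")
    return float(_stats.pearsonr(bp, dp).statistic)
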