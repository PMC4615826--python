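"""Ground-truth-known synthetic data for estimator and pipeline validation.

Two tiers of fixture are generated here:

* **Coupled process pairs** (:func:`gen_coupled_pair`,
  :func:`gen_nonlinear_pair`) — autoregressive pairs with a known
  directed coupling (linear or quadratic) at a known lag, used to
  validate the transfer-entropy estimator against closed-form Granger
  oracles and surrogate nulls.

* **Full driving sessions** (:func:`gen_session`) — six-channel
  "EEG-like" continuous records with per-trial lane-deviation events
  and reaction times.  A latent vigilance trajectory in [0, 1] drives
  three observable signatures of drowsiness: (i) reaction times grow
  and grow right-skewed (with rare multi-second "lapses" mimicking a
  driver who simply stops responding), (ii) low-frequency (delta,
  theta) band power rises while alpha and beta power falls, and
  (iii) directed channel couplings follow prescribed
  strength-vs-performance profiles — constant, inverted-U peaking at
  an intermediate driving-performance level, or monotonically
  decreasing toward deep drowsiness.

Every random draw flows from one seeded generator per call, so
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as _signal

from . import behavior
from .session import Session

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingTruth",
    "SessionConfig",
    "DEFAULT_CHANNELS",
    "gen_coupled_pair",
    "gen_nonlinear_pair",
    "gen_session",
    "band_weights",
    "default_vigilance_trajectory",
]

DEFAULT_CHANNELS = ("Fz", "Cz", "C3", "C4", "Pz", "Oz")
REQUIRED_CHANNELS = frozenset(DEFAULT_CHANNELS)

#: (low Hz, high Hz, center Hz) of the four classic EEG bands used in
#: the generator's oscillatory mixture.
_BAND_CENTERS = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 16.0}


def band_weights(v: float) -> dict[str, float]:
    """Mixing weight of each band oscillation at latent vigilance ``v``.

    Monotone by construction: as vigilance falls from 1 to 0, delta
    and theta weights rise while alpha and beta weights fall — the
    canonical spectral signature of drowsiness.  These weights are the
    generator's ground truth for the spectral contract (assertions
    belong on them, not on FFT estimates).
    """
    return {
        band: float(band_weights_arr(np.asarray(v, dtype=float), band))
        for band in _BAND_CENTERS
    }


@dataclass(frozen=True)
class CouplingTruth:
    """Ground-truth directed coupling for one ordered channel pair.

    ``strength_profile(dp)`` gives the dimensionless coupling
    coefficient mixing the (lagged) source channel's intrinsic signal
    into the sink, as a function of the trial's driving performance
    DP in [1, 4]:

    * ``constant`` — ``strength`` everywhere;
    * ``inverted_u`` — Gaussian bump of height ``strength`` centered
      at ``peak_dp`` (default 2.5) with scale ``width``;
    * ``monotone_decreasing`` — decline from ``strength`` at DP = 1
      to 0 at DP = 4 as ``strength * sqrt((4 - dp) / 3)``
      (non-increasing over the whole range).  Transfer entropy grows
      roughly with the squared coupling coefficient, so this shape
      makes the *information transfer* fall approximately linearly
      across the full performance range — the occipital pattern being
      emulated — instead of flattening into the noise floor early.

    ``lag`` is in samples at the generation rate.
    """

    source: str
    sink: str
    lag: int = 10
    strength: float = 0.8
    shape: str = "constant"
    peak_dp: float = 2.5
    width: float = 0.5

    def __post_init__(self):
        if self.lag < 1:
            raise ValueError("coupling lag must be >= 1 sample")
        if self.shape not in ("constant", "inverted_u", "monotone_decreasing"):
            raise ValueError(f"unknown profile shape {self.shape!r}")
        if self.source == self.sink:
            raise ValueError("coupling must join two distinct channels")

    def strength_profile(self, dp):
        dp = np.asarray(dp, dtype=float)
        if self.shape == "constant":
            out = np.full_like(dp, self.strength)
        elif self.shape == "inverted_u":
            out = self.strength * np.exp(
                -0.5 * ((dp - self.peak_dp) / self.width) ** 2
            )
        else:  # monotone_decreasing
            out = self.strength * np.sqrt(np.clip((4.0 - dp) / 3.0, 0.0, 1.0))
        return float(out) if out.ndim == 0 else out


def default_vigilance_trajectory(n_trials: int) -> Callable[[np.ndarray], np.ndarray]:
    """Alert-to-drowsy decline over the session with a gentle wobble.

    Vigilance starts near 1, declines roughly linearly to near 0 over
    the session and carries a slow sinusoidal fluctuation, so that
    trials cover the whole performance range with extra dwell time at
    intermediate levels (where the interesting connectivity changes
    live).
    """

    def traj(i):
        i = np.asarray(i, dtype=float)
        frac = i / max(n_trials - 1, 1)
        v = 1.0 - 0.98 * frac + 0.12 * np.sin(2.0 * np.pi * 2.5 * frac)
        return np.clip(v, 0.0, 1.0)

    return traj


@dataclass
class SessionConfig:
    """Parameters of a simulated sustained-attention driving session.

    Defaults mirror the recorded-study conditions: acquisition at
    500 Hz, 1-s baseline epochs, the next lane perturbation arriving
    5-10 s after the previous response, and right-skewed reaction
    times with rare very long lapses.
    """

    n_trials: int = 100
    fs: float = 500.0
    epoch_len: float = 1.0
    iti: tuple[float, float] = (5.0, 10.0)
    vigilance_trajectory: Callable | None = None
    rt_noise: float = 0.2          # lognormal sigma of the regular RT draw
    rt_alert: float = 0.7          # median RT (s) at full vigilance
    rt_slope: float = 2.2          # log-RT increase from v=1 to v=0
    lapse_prob_max: float = 0.08   # lapse probability as v -> 0
    lapse_range: tuple[float, float] = (10.0, 300.0)
    noise_floor: float = 0.35      # broadband (white) mixture weight
    channels: Sequence[str] = DEFAULT_CHANNELS
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        n_samp = self.epoch_len * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("epoch_len x fs must be an integer sample count")
        missing = REQUIRED_CHANNELS - set(self.channels)
        if missing:
            raise ValueError(
                f"channel set must include {sorted(REQUIRED_CHANNELS)}; "
                f"missing {sorted(missing)}"
            )


def _check_pair_args(n, a, b, lag):
    if abs(a) >= 1 or abs(b) >= 1:
        raise ValueError("AR coefficients must satisfy |a| < 1 and |b| < 1")
    if n < 1000:
        raise ValueError("n must be >= 1000 for a usable fixture")
    if lag < 1:
        raise ValueError("lag must be >= 1")


def _ar1(coef: float, innovations: np.ndarray) -> np.ndarray:
    return _signal.lfilter([1.0], [1.0, -coef], innovations)


def gen_coupled_pair(n: int, a: float = 0.5, b: float = 0.5, c: float = 0.5,
                     lag: int = 1, noise_sd: float = 1.0, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Linearly coupled AR(1) pair with strictly y -> x coupling.

        y_t = b y_{t-1} + eta_t
        x_t = a x_{t-1} + c y_{t-lag} + eps_t

    with independent Gaussian innovations of standard deviation
    ``noise_sd``.  A 500-sample burn-in removes transients.  For this
    jointly Gaussian system transfer entropy and Granger causality
    are analytically linked (TE = GC / 2 in nats), which makes the
    pair the primary estimator-validation fixture.
    """
    _check_pair_args(n, a, b, lag)
    rng = np.random.default_rng(seed)
    burn = 500
    total = n + burn + lag
    ey = noise_sd * rng.standard_normal(total)
    ex = noise_sd * rng.standard_normal(total)
    y = _ar1(b, ey)
    drive = np.zeros(total)
    drive[lag:] = c * y[:-lag]
    x = _ar1(a, ex + drive)
    return x[burn + lag:], y[burn + lag:]


def gen_nonlinear_pair(n: int, c: float = 0.8, lag: int = 1, seed: int = 0,
                       a: float = 0.5, b: float = 0.5, noise_sd: float = 1.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Quadratically coupled pair: y drives x through its square.

        x_t = a x_{t-1} + c (y_{t-lag})^2 + eps_t

    Because y is zero-mean (Gaussian AR(1)), the linear
    cross-correlation between x and the lagged y vanishes (all odd
    moments of y are zero) while the directed information flow
    y -> x is strictly positive — the canonical case where a
    model-free measure detects what a linear one cannot.
    """
    _check_pair_args(n, a, b, lag)
    rng = np.random.default_rng(seed)
    burn = 500
    total = n + burn + lag
    ey = noise_sd * rng.standard_normal(total)
    ex = noise_sd * rng.standard_normal(total)
    y = _ar1(b, ey)
    drive = np.zeros(total)
    drive[lag:] = c * y[:-lag] ** 2
    x = _ar1(a, ex + drive)
    return x[burn + lag:], y[burn + lag:]


def _band_oscillation(rng, n: int, center_hz: float, fs: float) -> np.ndarray:
    """Unit-variance narrow-band noise from an AR(2) resonator."""
    r = 0.985
    theta = 2.0 * math.pi * center_hz / fs
    a = [1.0, -2.0 * r * math.cos(theta), r * r]
    x = _signal.lfilter([1.0], a, rng.standard_normal(n + 500))[500:]
    return x / x.std()


def _draw_rts(rng, v: np.ndarray, cfg: SessionConfig) -> np.ndarray:
    """Reaction times: lognormal body plus vigilance-dependent lapses."""
    z = rng.standard_normal(v.size)
    rt = cfg.rt_alert * np.exp(cfg.rt_slope * (1.0 - v) + cfg.rt_noise * z)
    p_lapse = cfg.lapse_prob_max * (1.0 - v) ** 2
    lapse = rng.random(v.size) < p_lapse
    rt[lapse] = rng.uniform(*cfg.lapse_range, size=int(lapse.sum()))
    return rt


def gen_session(config: SessionConfig,
                truths: Sequence[CouplingTruth] = ()
                ) -> tuple[Session, "np.ndarray"]:
    """Simulate one subject's continuous session with known couplings.

    Returns ``(session, behavior_table)``.  The behavior table is the
    package's own per-trial table (rt, normalized rt, DP, group)
    computed from the generated RTs — there is exactly one definition
    of DP, and the ground-truth coupling strengths are evaluated at
    these DPs.

    Generation order:

    1. latent vigilance per trial from the trajectory;
    2. reaction times from the vigilance-dependent lognormal + lapse
       model, then DP via the behavior module;
    3. trial timeline — onset i follows the previous response offset
       by a uniform 5-10 s interval;
    4. per-channel intrinsic signals: four band-limited oscillations
       (delta/theta/alpha/beta) weighted by :func:`band_weights` of
       the trial's vigilance (piecewise-constant per trial), plus a
       broadband noise floor;
    5. directed couplings: each truth adds
       ``strength_profile(DP_trial) * intrinsic_source(t - lag)`` to
       its sink channel.
    """
    cfg = config
    for tr in truths:
        for lab in (tr.source, tr.sink):
            if lab not in cfg.channels:
                raise ValueError(f"coupling references unknown channel {lab!r}")
    rng = np.random.default_rng(cfg.seed)
    n_tr = cfg.n_trials
    traj = cfg.vigilance_trajectory or default_vigilance_trajectory(n_tr)
    v = np.clip(np.asarray(traj(np.arange(n_tr)), dtype=float), 0.0, 1.0)

    rts = _draw_rts(rng, v, cfg)
    table = behavior.behavior_table(rts)
    dps = table["dp"].to_numpy()

    # trial timeline (seconds)
    onsets_s = np.empty(n_tr)
    t = 2.0 * cfg.epoch_len  # lead-in so the first baseline exists
    for i in range(n_tr):
        t += rng.uniform(*cfg.iti)
        onsets_s[i] = t
        t += rts[i]
    n_samples = int(round((t + 1.0) * cfg.fs))
    onsets = np.round(onsets_s * cfg.fs).astype(int)

    # piecewise-constant per-trial envelopes on the sample grid:
    # trial i owns samples up to its response offset
    ends = np.round((onsets_s + rts) * cfg.fs).astype(int)
    trial_of_sample = np.searchsorted(ends, np.arange(n_samples), side="left")
    trial_of_sample = np.minimum(trial_of_sample, n_tr - 1)
    v_env = v[trial_of_sample]

    max_lag = max((tr.lag for tr in truths), default=0)
    channels = list(cfg.channels)
    intrinsic = np.empty((len(channels), n_samples + max_lag))
    weights = {band: band_weights_arr(v_env, band) for band in _BAND_CENTERS}
    for ci in range(len(channels)):
        acc = cfg.noise_floor * rng.standard_normal(n_samples + max_lag)
        for band, f0 in _BAND_CENTERS.items():
            osc = _band_oscillation(rng, n_samples + max_lag, f0, cfg.fs)
            w = weights[band]
            acc[max_lag:] += w * osc[max_lag:]
            acc[:max_lag] += (w[0] if w.ndim else w) * osc[:max_lag]
        intrinsic[ci] = acc

    data = intrinsic[:, max_lag:].copy()
    for tr in truths:
        s_env = tr.strength_profile(dps)[trial_of_sample]
        si = channels.index(tr.source)
        ki = channels.index(tr.sink)
        lagged = intrinsic[si, max_lag - tr.lag: max_lag - tr.lag + n_samples]
        data[ki] += s_env * lagged

    meta = {
        "seed": cfg.seed,
        "vigilance": v.tolist(),
        "dp": dps.tolist(),
        "truths": [
            {
                "source": tr.source, "sink": tr.sink, "lag": tr.lag,
                "strength": tr.strength, "shape": tr.shape,
                "peak_dp": tr.peak_dp, "width": tr.width,
            }
            for tr in truths
        ],
        "generator": "drowsyte.synth.gen_session",
    }
    session = Session(
        data=data, fs=cfg.fs, channels=channels, onsets=onsets, rts=rts,
        meta=meta,
    )
    return session, table


def band_weights_arr(v: np.ndarray, band: str) -> np.ndarray:
    """Vectorized :func:`band_weights` for one band."""
    drowsiness = 1.0 - np.asarray(v, dtype=float)
    coeffs = {
        "delta": (0.50, +1.10),
        "theta": (0.50, +0.60),
        "alpha": (0.95, -0.65),
        "beta": (0.70, -0.50),
    }[band]
    return coeffs[0] + coeffs[1] * drowsiness
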