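"""Band-pass filtering, downsampling, baseline epoching, time-shift screen.

The analysis chain operates on the 1-s pre-stimulus ("baseline")
window of every trial: tonic EEG in that window reflects the
vigilance state in which the upcoming lane perturbation will be
handled.  Before epoching, the continuous record is band-pass
filtered 1-50 Hz with a zero-phase FIR filter (forward-backward
application of a windowed-sinc design) and decimated from the
acquisition rate to 250 Hz.

The time-shift screen guards against instantaneous mixing (volume
conduction): if shifting the source one sample forward *increases*
the apparent transfer entropy into the sink, the dominant dependence
between the pair is instantaneous rather than time-lagged and the
pair is rejected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session import Epochs, Session
from .te import EmbeddingSpec, ksg_te

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "design_fir",
    "bandpass_zero_phase",
    "downsample",
    "extract_baseline_epochs",
    "time_shift_test",
]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase band-pass FIR specification.

    ``n_taps`` defaults to the classic EEG-toolbox heuristic
    ``3 * fs / low_cut`` (rounded up to odd), which at 500 Hz and a
    1 Hz low edge gives a 1501-tap linear-phase filter.
    """

    low_cut: float = 1.0
    high_cut: float = 50.0
    n_taps: int | None = None

    def resolve_taps(self, fs: float) -> int:
        if not (0 < self.low_cut < self.high_cut < fs / 2):
            raise ValueError(
                f"cutoffs ({self.low_cut}, {self.high_cut}) Hz invalid for "
                f"fs={fs} Hz"
            )
        n = self.n_taps if self.n_taps is not None else int(
            round(3 * fs / self.low_cut)
        )
        return n + 1 if n % 2 == 0 else n  # odd -> type-I linear phase


def design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass taps for the given rate."""
    n_taps = spec.resolve_taps(fs)
    return signal.firwin(
        n_taps, [spec.low_cut, spec.high_cut], pass_zero=False, fs=fs
    )


def bandpass_zero_phase(x, fs: float, spec: FilterSpec | None = None
                        ) -> np.ndarray:
    """Forward-backward band-pass filtering along the last axis.

    Applying the symmetric FIR forward and backward equals a single
    zero-phase convolution with the filter's autocorrelation, so the
    magnitude response is squared (stop-band attenuation doubles in
    dB) and the net group delay is zero.  Edges are padded with the
    odd reflection of the signal, as conventional for zero-phase
    filtering.  Output length equals input length.
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    b = design_fir(spec, fs)
    order = b.size - 1
    n = x.shape[-1]
    if n <= 3 * order:
        raise ValueError(
            f"signal length {n} too short for filter order {order} "
            f"(need > {3 * order} samples)"
        )
    pad = order
    # odd reflection around the end points
    left = 2 * x[..., :1] - x[..., pad:0:-1]
    right = 2 * x[..., -1:] - x[..., -2: -pad - 2: -1]
    xp = np.concatenate([left, x, right], axis=-1)
    h = np.convolve(b, b[::-1])  # zero-phase composite kernel
    y = signal.fftconvolve(xp, h[(np.newaxis,) * (x.ndim - 1)], mode="same",
                           axes=-1)
    return y[..., pad: pad + n]


def downsample(x, fs_in: float, fs_out: float) -> np.ndarray:
    """Decimate by an integer factor (last axis); no extra filtering.

    The caller is responsible for having low-passed the signal below
    the new Nyquist (the band-pass stage does).  Sample ``k`` of the
    output is sample ``k * factor`` of the input.
    """
    ratio = fs_in / fs_out
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"decimation factor {ratio:g} (fs {fs_in} -> {fs_out}) is not a "
            "positive integer"
        )
    x = np.asarray(x)
    return x[..., ::factor]


def extract_baseline_epochs(session: Session, epoch_len: float = 1.0
                            ) -> Epochs:
    """Cut the pre-onset baseline window of every trial.

    Each epoch is the half-open window ``[onset - epoch_len, onset)``
    — exactly ``epoch_len * fs`` samples ending one sample before the
    deviation onset, so no post-onset sample is ever read.  Trials
    whose onset is closer than ``epoch_len`` to the start of the
    recording are dropped with a logged warning.
    """
    n_samp = epoch_len * session.fs
    if abs(n_samp - round(n_samp)) > 1e-9:
        raise ValueError(
            f"epoch_len {epoch_len}s x fs {session.fs} Hz is not an integer "
            "sample count"
        )
    n_samp = int(round(n_samp))
    kept, slices = [], []
    for i, onset in enumerate(np.asarray(session.onsets, dtype=int)):
        if onset - n_samp < 0:
            logger.warning(
                "trial %d dropped: onset sample %d leaves no room for a "
                "%d-sample baseline", i, onset, n_samp,
            )
            continue
        kept.append(i)
        slices.append(session.data[:, onset - n_samp: onset])
    if not kept:
        data = np.empty((session.data.shape[0], 0, n_samp))
    else:
        data = np.stack(slices, axis=1)
    return Epochs(
        data=data,
        fs=session.fs,
        channels=list(session.channels),
        trial_index=np.asarray(kept, dtype=int),
        meta=dict(session.meta, epoch_len=epoch_len),
    )


def time_shift_test(x_epochs, y_epochs, spec: EmbeddingSpec | None = None,
                    n_perm: int = 500, shift: int = 1, alpha: float = 0.05,
                    seed: int | None = None) -> tuple[bool, float]:
    """Screen the ordered pair (source y -> sink x) for instantaneous mixing.

    Per trial, TE(y -> x) is estimated twice: from the source as
    recorded and from the source advanced by ``shift`` samples (so
    that the sample simultaneous with the predicted sink sample enters
    the source state).  Under instantaneous mixing the shifted source
    "predicts" the sink better; under genuine lagged coupling it does
    not.  A one-sided paired sign-flip permutation test on the
    per-trial differences (shifted minus unshifted) gives the
    p-value; the pair is rejected when p < alpha.

    Returns ``(passed, p_value)`` — ``passed`` is True when no
    instantaneous mixing is detected.
    """
    spec = spec or EmbeddingSpec()
    x = np.atleast_2d(np.asarray(x_epochs, dtype=float))
    y = np.atleast_2d(np.asarray(y_epochs, dtype=float))
    if x.shape != y.shape:
        raise ValueError("epoch arrays must have identical shapes")
    if x.shape[1] <= spec.horizon + spec.u + shift + spec.k + 1:
        raise ValueError("epochs shorter than the embedding horizon")
    diffs = []
    for i in range(x.shape[0]):
        te_plain = ksg_te(y[i, :-shift], x[i, :-shift], spec).value
        te_shift = ksg_te(y[i, shift:], x[i, :-shift], spec).value
        diffs.append(te_shift - te_plain)
    diffs = np.asarray(diffs)
    observed = diffs.mean()
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diffs.size))
    null = (signs * diffs).mean(axis=1)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return bool(p >= alpha), float(p)
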