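"""Reaction-time normalization and the driving-performance (DP) index.

Raw reaction times (RTs) from a sustained-attention driving task are
heavily right-skewed: an alert driver corrects a lane perturbation in
well under a second, while a drowsy one may take tens or hundreds of
seconds.  Two transforms tame this scale for downstream statistics:

1. *Normalization* — each subject's RTs are divided by the mean of
   their fastest decile, so that optimal performance maps to ~1
   regardless of individual baseline speed.  Values below 1 are
   clipped to 1 (the subject is unambiguously alert).
2. *DP transform* — a bounded logistic map of the normalized RT onto
   the driving-performance index.  DP(1) = 1, DP grows nearly
   linearly up to normalized RT ~2.5 (DP = 2.26), reaches 3.11 at
   normalized RT 4, and saturates at ~4.08 as RT grows without bound,
   so that a 300 s lapse and a 10 s lapse count as comparably "poor".

Performance groups: optimal (DP < 2), sub-optimal (2 <= DP <= 3),
poor (DP > 3).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DP_OFFSET",
    "DP_SCALE",
    "DP_SUPREMUM",
    "normalize_rts",
    "dp_transform",
    "dp_inverse",
    "assign_group",
    "baseline_trial_indices",
    "behavior_table",
]

_E = math.exp(-0.5)
#: Additive constant of the logistic DP map, (1 + e^-1/2) / (1 - e^-1/2).
DP_OFFSET = (1.0 + _E) / (1.0 - _E)
#: Multiplicative constant, (2 + 2 e^-1/2) / (1 - e^-1/2) = 2 * DP_OFFSET.
DP_SCALE = (2.0 + 2.0 * _E) / (1.0 - _E)
#: Least upper bound of DP: the limit of the transform as RT -> inf.
DP_SUPREMUM = DP_SCALE - DP_OFFSET

GROUP_LABELS = ("optimal", "sub_optimal", "poor")


def _top_decile_count(n: int) -> int:
    """Number of trials in the "fastest 10%": ceil(0.1 * n), at least 1."""
    return max(1, math.ceil(0.1 * n))


def normalize_rts(rts) -> np.ndarray:
    """Normalize RTs by the mean of the fastest decile, clipping below at 1.

    Parameters
    ----------
    rts : array-like of float
        Per-trial reaction times in seconds; all strictly positive.

    Returns
    -------
    ndarray
        Normalized RTs, each >= 1.

    Notes
    -----
    The denominator is the mean of the ``ceil(0.1 * N)`` smallest RTs
    (ties broken by ascending trial index).  Any ratio below 1 is set
    to 1: a response faster than the subject's own alert baseline is
    still "alert".  The result is invariant to rescaling all RTs by a
    common positive factor.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("empty RT list")
    if not np.all(np.isfinite(rts)) or np.any(rts <= 0):
        raise ValueError("all RTs must be finite and > 0")
    n = rts.size
    if n < 10:
        logger.warning(
            "normalize_rts called with %d trials (< 10); the fastest-decile "
            "denominator rests on %d trial(s)", n, _top_decile_count(n),
        )
    k = _top_decile_count(n)
    fastest = np.sort(rts, kind="stable")[:k]
    denom = float(fastest.mean())
    return np.maximum(rts / denom, 1.0)


def dp_transform(nrt):
    """Map normalized RT to the driving-performance index.

    DP = -(1 + e^-0.5)/(1 - e^-0.5)
         + (2 + 2 e^-0.5)/(1 - e^-0.5) * 1 / (1 + e^(-0.5 * nrt))

    Monotone increasing on [1, inf); DP(1) = 1 and DP < ~4.0833.
    Accepts scalars or arrays.
    """
    nrt_arr = np.asarray(nrt, dtype=float)
    if np.any(nrt_arr < 1.0 - 1e-12):
        raise ValueError("normalized RT must be >= 1 (clip upstream)")
    dp = -DP_OFFSET + DP_SCALE / (1.0 + np.exp(-0.5 * nrt_arr))
    return float(dp) if np.isscalar(nrt) or np.ndim(nrt) == 0 else dp


def dp_inverse(dp):
    """Invert the DP transform back to normalized RT.

    Defined for DP in [1, DP_SUPREMUM).
    """
    dp_arr = np.asarray(dp, dtype=float)
    if np.any(dp_arr < 1.0 - 1e-9) or np.any(dp_arr >= DP_SUPREMUM):
        raise ValueError("dp must lie in [1, DP_SUPREMUM)")
    q = DP_SCALE / (dp_arr + DP_OFFSET) - 1.0
    nrt = -2.0 * np.log(q)
    return float(nrt) if np.isscalar(dp) or np.ndim(dp) == 0 else nrt


def assign_group(dp):
    """Classify DP into optimal (< 2), sub_optimal (2..3 incl.), poor (> 3)."""
    dp_arr = np.asarray(dp, dtype=float)
    if np.any(dp_arr < 1.0 - 1e-9):
        raise ValueError("dp must be >= 1")
    out = np.where(dp_arr < 2.0, "optimal",
                   np.where(dp_arr <= 3.0, "sub_optimal", "poor"))
    if np.isscalar(dp) or np.ndim(dp) == 0:
        return str(out)
    return out.astype(object)


def baseline_trial_indices(dps) -> np.ndarray:
    """Indices of the best-performance trials: smallest ceil(0.1*N) DPs.

    These trials define the per-subject connectivity baseline.  Ties
    are broken by ascending trial index (stable sort).
    """
    dps = np.asarray(dps, dtype=float)
    if dps.size == 0:
        raise ValueError("empty DP list")
    if dps.size < 10:
        logger.warning(
            "baseline_trial_indices on %d trials (< 10): baseline is %d "
            "trial(s)", dps.size, _top_decile_count(dps.size),
        )
    k = _top_decile_count(dps.size)
    return np.argsort(dps, kind="stable")[:k]


def behavior_table(rts) -> pd.DataFrame:
    """Full per-trial behavior table: rt, normalized rt, DP, group.

    Columns: ``trial_index`` (1-based), ``rt_s``, ``normalized_rt``,
    ``dp``, ``group``.
    """
    rts = np.asarray(rts, dtype=float)
    nrt = normalize_rts(rts)
    dp = dp_transform(nrt)
    return pd.DataFrame(
        {
            "trial_index": np.arange(1, rts.size + 1),
            "rt_s": rts,
            "normalized_rt": nrt,
            "dp": dp,
            "group": assign_group(dp),
        }
    )
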