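"""Kraskov k-nearest-neighbor transfer entropy between channel pairs.

Transfer entropy TE(Y -> X) quantifies the directed information flow
from a source process Y to a sink process X: the reduction in
uncertainty about the sink's future sample ``x_{t+u}`` obtained from
the source's delay-embedded past ``y_t^m``, beyond what the sink's own
past ``x_t^d`` already provides.  Formally it is the conditional
mutual information

    TE(Y -> X) = I(x_{t+u} ; y_t^m | x_t^d)

which is zero when the processes are independent and is inherently
asymmetric under unidirectional coupling.

The estimator here is the Kraskov-Stoegbauer-Grassberger (KSG)
k-nearest-neighbor scheme in its conditional-mutual-information form
(single combined neighbor search with algorithm-1 counting), using
the Chebyshev (max) norm and a Theiler window that excludes
temporally adjacent state vectors from all neighbor searches and
counts.  Natural logarithms are used internally; results are reported
in bits.

Small negative estimates are possible (estimator bias); the
population quantity is non-negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingSpec",
    "TEResult",
    "delay_embed",
    "select_delay",
    "cao_statistics",
    "cao_dimension",
    "ksg_te",
    "ksg_te_epochs",
    "select_u",
    "surrogate_test",
    "ms_to_samples",
]

#: Prediction-time search grid, in milliseconds.
DEFAULT_U_CANDIDATES_MS = (5, 10, 20, 40, 60, 80, 100)


@dataclass(frozen=True)
class EmbeddingSpec:
    """State-space reconstruction parameters for TE estimation.

    Attributes
    ----------
    d : int
        Sink embedding dimension.
    m : int
        Source embedding dimension.
    tau : int
        Embedding delay in samples (shared by source and sink).
    u : int
        Prediction time in samples: the sink sample predicted is
        ``u`` samples ahead of the embedded states.
    k : int
        Neighbor count of the KSG estimator (4 is the conventional
        choice).
    theiler : int
        Theiler exclusion window T: vectors within ``|t - t'| <= T``
        of a reference vector are excluded from neighbor searches to
        suppress autocorrelation bias.
    """

    d: int = 2
    m: int = 2
    tau: int = 1
    u: int = 1
    k: int = 4
    theiler: int = 1

    def __post_init__(self):
        if self.d < 1 or self.m < 1:
            raise ValueError("embedding dimensions d, m must be >= 1")
        if self.tau < 1 or self.u < 1:
            raise ValueError("tau and u must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.theiler < 0:
            raise ValueError("theiler must be >= 0")

    @property
    def horizon(self) -> int:
        """Samples consumed before the first usable state vector."""
        return (max(self.d, self.m) - 1) * self.tau

    def replace(self, **kw) -> "EmbeddingSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class TEResult:
    """A single directed transfer-entropy estimate.

    ``value`` is in bits; ``direction`` is the ordered
    (source, sink) pair; ``n_effective`` counts the state vectors
    actually used.
    """

    value: float
    direction: tuple[str, str] = ("source", "sink")
    spec: EmbeddingSpec = field(default_factory=EmbeddingSpec)
    n_effective: int = 0


def delay_embed(x, dim: int, tau: int) -> np.ndarray:
    """Delay-coordinate embedding: row t = (x_t, x_{t-tau}, ..., x_{t-(dim-1)tau}).

    Returns an array of shape ``(len(x) - (dim-1)*tau, dim)``; the
    first row corresponds to time index ``(dim-1)*tau`` of the input.
    """
    x = np.asarray(x, dtype=float)
    if dim < 1 or tau < 1:
        raise ValueError("dim and tau must be >= 1")
    span = (dim - 1) * tau
    if x.size < span + 1:
        raise ValueError(
            f"series of length {x.size} too short for dim={dim}, tau={tau}"
        )
    cols = [x[span - j * tau: x.size - j * tau] for j in range(dim)]
    return np.column_stack(cols)


def select_delay(x, max_lag: int | None = None) -> int:
    """Embedding delay: first lag at which autocorrelation drops below 1/e.

    The literature attaches embedding-parameter choice to Cao's
    method, which in its original form selects the *dimension*; for
    the *delay* the common companion rule — first autocorrelation
    crossing of 1/e — is used here.  Always returns >= 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("series too short for delay selection")
    xc = x - x.mean()
    v = float(xc @ xc)
    if v == 0.0:
        raise ValueError("constant series: autocorrelation undefined")
    if max_lag is None:
        max_lag = min(x.size // 4, 500)
    thresh = 1.0 / math.e
    for lag in range(1, max_lag + 1):
        r = float(xc[:-lag] @ xc[lag:]) / v
        if r < thresh:
            return lag
    logger.warning("autocorrelation never fell below 1/e up to lag %d; "
                   "returning %d", max_lag, max_lag)
    return max_lag


def cao_statistics(x, tau: int, d_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Cao's E1 and E2 statistics for dimensions d = 1 .. d_max-1.

    ``E1[d-1] = E(d+1)/E(d)`` where E(d) is the mean ratio of
    (d+1)-dimensional to d-dimensional Chebyshev distances between
    each embedded point and its d-dimensional nearest neighbor.  E1
    saturates near 1 once the attractor is unfolded.  ``E2`` is the
    analogous ratio built from the single extra coordinate; for a
    purely stochastic series E2 stays near 1 for every d.
    """
    x = np.asarray(x, dtype=float)
    if d_max < 2:
        raise ValueError("d_max must be >= 2")
    span_max = d_max * tau  # embedding at d_max+1 needs d_max*tau history
    if x.size < span_max + 10:
        raise ValueError("series too short for the requested d_max")
    if np.ptp(x) == 0:
        raise ValueError("constant series")

    # Align all embeddings on the same time indices (t >= d_max*tau).
    n_vec = x.size - span_max
    emb = {d: delay_embed(x, d, tau)[-n_vec:] for d in range(1, d_max + 2)}

    E = np.empty(d_max)
    Estar = np.empty(d_max)
    for d in range(1, d_max + 1):
        pts = emb[d]
        tree = cKDTree(pts)
        k_query = min(len(pts), 8)
        dist, idx = tree.query(pts, k=k_query, p=np.inf)
        # nearest distinct neighbor with nonzero distance
        nn = np.full(len(pts), -1)
        nnd = np.empty(len(pts))
        for j in range(1, k_query):
            unset = nn < 0
            ok = unset & (dist[:, j] > 0)
            nn[ok] = idx[ok, j]
            nnd[ok] = dist[ok, j]
        good = nn >= 0
        if good.sum() < 10:
            raise ValueError("too many duplicate state vectors for Cao statistics")
        nn_g = nn[good]
        d1 = np.max(np.abs(emb[d + 1][good] - emb[d + 1][nn_g]), axis=1)
        E[d - 1] = float(np.mean(d1 / nnd[good]))
        # extra-coordinate distance: first column of the (d+1)-embedding
        # is the most recent sample; the added coordinate is the last.
        extra = np.abs(emb[d + 1][good, -1] - emb[d + 1][nn_g, -1])
        Estar[d - 1] = float(np.mean(extra))
    E1 = E[1:d_max] / E[: d_max - 1]
    E2 = Estar[1:d_max] / Estar[: d_max - 1]
    return E1, E2


def cao_dimension(x, tau: int, d_max: int = 8, tol: float = 0.05) -> int:
    """Smallest embedding dimension at which Cao's E1 saturates.

    Returns the first ``d`` with ``|E1(d) - 1| < tol``, capped at
    ``d_max``.  For stochastic series E1 approaches 1 slowly and the
    cap applies.
    """
    E1, _ = cao_statistics(x, tau, d_max)
    for d in range(1, d_max):
        if abs(E1[d - 1] - 1.0) < tol:
            return d
    logger.info("Cao E1 did not saturate below d_max=%d; capping", d_max)
    return d_max


# ---------------------------------------------------------------------------
# KSG conditional-mutual-information core
# ---------------------------------------------------------------------------

def _ksg_cmi(target: np.ndarray, ystate: np.ndarray, xstate: np.ndarray,
             tidx: np.ndarray, k: int, theiler: int) -> float:
    """KSG estimate (nats) of I(target ; ystate | xstate).

    ``tidx`` holds the time index of every state vector; vectors with
    ``|tidx_i - tidx_j| <= theiler`` are mutually excluded from the
    k-nearest-neighbor search and from all marginal counts (vectors
    from different trials carry far-apart indices and are never
    excluded).
    """
    n = target.size
    joint = np.column_stack([target, ystate, xstate])
    # Enough neighbors to survive dropping self + up to 2*theiler
    # temporally adjacent vectors.
    k_query = min(n, k + 2 * theiler + 2)
    dist, idx = cKDTree(joint).query(joint, k=k_query, p=np.inf)
    if k_query == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    valid = np.abs(tidx[idx] - tidx[:, None]) > theiler
    n_valid = valid.sum(axis=1)
    if np.any(n_valid < k):
        raise ValueError(
            "series too short for the requested k and Theiler window"
        )
    rows = np.arange(n)
    kth = (valid.cumsum(axis=1) == k).argmax(axis=1)
    eps = dist[rows, kth]
    radius = np.nextafter(eps, 0.0)  # strict inequality, KSG algorithm 1

    order = np.argsort(tidx, kind="stable")

    def _count(pts: np.ndarray) -> np.ndarray:
        c = cKDTree(pts).query_ball_point(
            pts, radius, p=np.inf, return_length=True
        ).astype(np.int64)
        # remove self and Theiler-window companions that fell inside
        srt_t = tidx[order]
        for off in range(-theiler, theiler + 1):
            pos = np.searchsorted(srt_t, tidx + off)
            ok = (pos < n) & (srt_t[np.minimum(pos, n - 1)] == tidx + off)
            i = rows[ok]
            j = order[pos[ok]]
            dd = np.max(np.abs(pts[i] - pts[j]), axis=1)
            c[i] -= dd <= radius[i]
        return c

    n_xz = _count(np.column_stack([target, xstate]))
    n_yz = _count(np.column_stack([ystate, xstate]))
    n_z = _count(xstate if xstate.ndim == 2 else xstate[:, None])
    return float(
        digamma(k)
        + np.mean(digamma(n_z + 1) - digamma(n_xz + 1) - digamma(n_yz + 1))
    )


def _check_series(name: str, x: np.ndarray):
    if np.any(~np.isfinite(x)):
        raise ValueError(f"{name} contains NaN or infinite samples")
    if np.ptp(x) == 0:
        raise ValueError(f"{name} has zero variance")


def _embed_pair(source: np.ndarray, sink: np.ndarray, spec: EmbeddingSpec,
                t_offset: int = 0):
    """Build (target, ystate, xstate, tidx) for one continuous segment.

    Both series are z-scored first, so the Chebyshev neighbor metric
    weighs source and sink coordinates comparably and the estimate is
    exactly invariant under separate affine rescaling of either
    series.
    """
    source = (source - source.mean()) / source.std()
    sink = (sink - sink.mean()) / sink.std()
    n = sink.size
    start = spec.horizon
    last = n - 1 - spec.u
    if last < start:
        raise ValueError(
            f"series of length {n} shorter than embedding horizon "
            f"{spec.horizon} + u={spec.u}"
        )
    xs = delay_embed(sink, spec.d, spec.tau)
    ys = delay_embed(source, spec.m, spec.tau)
    n_vec = last - start + 1
    xs = xs[start - (spec.d - 1) * spec.tau:][:n_vec]
    ys = ys[start - (spec.m - 1) * spec.tau:][:n_vec]
    target = sink[start + spec.u: start + spec.u + n_vec]
    tidx = np.arange(start, start + n_vec) + t_offset
    return target, ys, xs, tidx


def ksg_te(source, sink, spec: EmbeddingSpec | None = None) -> TEResult:
    """Transfer entropy TE(source -> sink) in bits for one segment.

    Both inputs are equal-length 1-D arrays (a single trial epoch or a
    long continuous record).  See the module docstring for the
    estimator; small negative values are within estimator bias.
    """
    spec = spec or EmbeddingSpec()
    source = np.asarray(source, dtype=float)
    sink = np.asarray(sink, dtype=float)
    if source.shape != sink.shape or source.ndim != 1:
        raise ValueError("source and sink must be equal-length 1-D arrays")
    _check_series("source", source)
    _check_series("sink", sink)
    target, ys, xs, tidx = _embed_pair(source, sink, spec)
    val = _ksg_cmi(target, ys, xs, tidx, spec.k, spec.theiler) / math.log(2)
    return TEResult(value=val, spec=spec, n_effective=target.size)


def ksg_te_epochs(source_epochs, sink_epochs, spec: EmbeddingSpec | None = None
                  ) -> TEResult:
    """Pooled TE over trials: state vectors concatenated across epochs.

    Rows of the 2-D inputs are trials.  Per-trial time indices are
    offset so the Theiler window never spans a trial boundary, i.e.
    neighbors from other trials are admissible (they are temporally
    independent) while within-trial temporal neighbors are excluded.
    """
    spec = spec or EmbeddingSpec()
    se = np.atleast_2d(np.asarray(source_epochs, dtype=float))
    ke = np.atleast_2d(np.asarray(sink_epochs, dtype=float))
    if se.shape != ke.shape:
        raise ValueError("source and sink epoch arrays must match in shape")
    parts = []
    gap = ke.shape[1] + spec.theiler + 1
    for i in range(se.shape[0]):
        _check_series(f"source trial {i}", se[i])
        _check_series(f"sink trial {i}", ke[i])
        parts.append(_embed_pair(se[i], ke[i], spec, t_offset=i * gap))
    target = np.concatenate([p[0] for p in parts])
    ys = np.vstack([p[1] for p in parts])
    xs = np.vstack([p[2] for p in parts])
    tidx = np.concatenate([p[3] for p in parts])
    val = _ksg_cmi(target, ys, xs, tidx, spec.k, spec.theiler) / math.log(2)
    return TEResult(value=val, spec=spec, n_effective=target.size)


def ms_to_samples(ms: float, fs: float) -> int:
    """Convert milliseconds to samples, round-half-up, floor at 1."""
    return max(1, int(math.floor(ms * fs / 1000.0 + 0.5)))


def select_u(source, sink, spec: EmbeddingSpec,
             candidates_ms=DEFAULT_U_CANDIDATES_MS, fs: float = 250.0
             ) -> tuple[int, dict[int, float]]:
    """Prediction time maximizing TE over a candidate grid.

    Candidates are given in milliseconds and converted at ``fs``
    (round-half-up, minimum 1 sample).  Ties break toward the
    smallest u.  Returns ``(u_samples, {u_samples: te_bits})``.
    """
    if len(candidates_ms) == 0:
        raise ValueError("empty candidate list")
    cand = sorted({ms_to_samples(ms, fs) for ms in candidates_ms})
    source = np.atleast_2d(np.asarray(source, dtype=float))
    sink = np.atleast_2d(np.asarray(sink, dtype=float))
    scores: dict[int, float] = {}
    best_u, best_te = None, -np.inf
    for u in cand:
        try:
            te = ksg_te_epochs(source, sink, spec.replace(u=u)).value
        except ValueError:
            continue  # candidate exceeds usable length
        scores[u] = te
        if te > best_te:  # strict: ties keep the smaller u
            best_u, best_te = u, te
    if best_u is None:
        raise ValueError("all prediction-time candidates exceed series length")
    return best_u, scores


def surrogate_test(source, sink, spec: EmbeddingSpec | None = None,
                   n_perm: int = 200, seed: int | None = None,
                   n_chunks: int | None = None) -> tuple[float, float, np.ndarray]:
    """Permutation significance test of TE(source -> sink).

    The observed statistic is the mean per-trial TE over matched
    (source, sink) trial pairs.  The null is built by shuffling the
    assignment of source trials to sink trials; because the statistic
    is a mean of per-(i, j) cross-trial TEs, the full cross-pair TE
    matrix is computed once and each permutation is then a cheap
    re-indexing.  For a single continuous pair, pass ``n_chunks`` to
    split it into pseudo-trials first; otherwise a circular-shift
    null is used (one full re-estimate per permutation).

    Returns ``(p_value, observed_te_bits, null_values)`` with
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    spec = spec or EmbeddingSpec()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    src = np.asarray(source, dtype=float)
    snk = np.asarray(sink, dtype=float)
    if src.ndim == 1 and n_chunks:
        usable = (src.size // n_chunks) * n_chunks
        src = src[:usable].reshape(n_chunks, -1)
        snk = snk[:usable].reshape(n_chunks, -1)

    if src.ndim == 2:
        n_tr = src.shape[0]
        if n_tr < 5:
            raise ValueError("need >= 5 trials for a trial-shuffle null")
        cross = np.empty((n_tr, n_tr))
        for i in range(n_tr):       # sink trial
            for j in range(n_tr):   # source trial
                cross[i, j] = ksg_te(src[j], snk[i], spec).value
        observed = float(np.mean(np.diag(cross)))
        rows = np.arange(n_tr)
        null = np.empty(n_perm)
        for p in range(n_perm):
            perm = rng.permutation(n_tr)
            null[p] = cross[rows, perm].mean()
    else:
        n = src.size
        margin = spec.horizon + spec.u + 10
        if n < 4 * margin:
            raise ValueError("series too short for a circular-shift null")
        observed = ksg_te(src, snk, spec).value
        null = np.empty(n_perm)
        for p in range(n_perm):
            shift = int(rng.integers(margin, n - margin))
            null[p] = ksg_te(np.roll(src, shift), snk, spec).value

    pval = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return float(pval), observed, null
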