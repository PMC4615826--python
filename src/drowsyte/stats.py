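"""Statistical surface: baseline-relative TE, DP-window profiles, FDR,
and three-group comparisons.

Per-trial connectivity values are first re-expressed *relative to the
subject's alert baseline* (mean over the best-tenth-percentile-DP
trials), pooled across subjects, sorted by driving performance, and
smoothed with an overlapping moving window (width 0.5 DP, step 0.1 DP
over [1, 4] — 26 windows, the first being DP 1.0-1.5).  Each window
is compared against the first with a two-sided Wilcoxon rank-sum
test; the resulting p-values are Benjamini-Hochberg adjusted.

Group analysis: per-subject mean relative TE in the optimal /
sub-optimal / poor performance groups, compared by one-way
repeated-measures ANOVA (sphericity assumed) and pairwise Wilcoxon
signed-rank tests with BH adjustment across the three contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "DPWindowProfile",
    "relative_te",
    "dp_windows",
    "window_ranksum_vs_first",
    "bh_fdr",
    "apply_window_fdr",
    "group_summarize",
    "rm_anova",
    "pairwise_signed_rank",
]

GROUP_ORDER = ("optimal", "sub_optimal", "poor")
PAIRWISE_CONTRASTS = (
    ("optimal", "sub_optimal"),
    ("sub_optimal", "poor"),
    ("optimal", "poor"),
)


@dataclass
class DPWindowProfile:
    """Moving-window summary of a value against driving performance.

    ``members[j]`` holds the values of trials whose DP falls in
    window j (``[lo_j, hi_j)``, the final window closed above).
    ``mean`` is NaN for empty windows.  ``p_raw``/``p_adj`` are
    filled by :func:`window_ranksum_vs_first` and :func:`bh_fdr`.
    """

    window_lo: np.ndarray
    window_hi: np.ndarray
    members: list[np.ndarray]
    mean: np.ndarray
    n: np.ndarray
    p_raw: np.ndarray | None = None
    p_adj: np.ndarray | None = None
    alpha: float = 0.001
    meta: dict = field(default_factory=dict)

    @property
    def center(self) -> np.ndarray:
        return (self.window_lo + self.window_hi) / 2.0

    @property
    def significant(self) -> np.ndarray:
        if self.p_adj is None:
            raise ValueError("run the rank-sum + FDR steps first")
        with np.errstate(invalid="ignore"):
            return self.p_adj < self.alpha

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "window_lo": self.window_lo,
            "window_hi": self.window_hi,
            "center": self.center,
            "n": self.n,
            "mean": self.mean,
        }
        if self.p_raw is not None:
            cols["p_raw"] = self.p_raw
        if self.p_adj is not None:
            cols["p_adj"] = self.p_adj
            cols["significant"] = self.significant
        return pd.DataFrame(cols)


def relative_te(values, baseline_idx) -> np.ndarray:
    """Subtract the mean over baseline trials from every trial's value."""
    values = np.asarray(values, dtype=float)
    idx = np.asarray(baseline_idx, dtype=int)
    if idx.size == 0:
        raise ValueError("empty baseline index set")
    if idx.min() < 0 or idx.max() >= values.size:
        raise ValueError("baseline index out of range")
    return values - values[idx].mean()


def dp_windows(dps, values, width: float = 0.5, step: float = 0.1,
               lo: float = 1.0, hi: float = 4.0) -> DPWindowProfile:
    """Bin values into overlapping DP windows.

    Window j covers ``[lo + j*step, lo + j*step + width)``; the last
    window's upper edge coincides with ``hi`` and is closed, so a
    trial at exactly DP = hi is counted there.  With the defaults
    this yields 26 windows, [1.0, 1.5] through [3.5, 4.0].
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    dps = np.asarray(dps, dtype=float)
    values = np.asarray(values, dtype=float)
    if dps.shape != values.shape:
        raise ValueError("dps and values must align")
    n_win = int(round((hi - lo - width) / step)) + 1
    los = lo + step * np.arange(n_win)
    his = los + width
    members, means, counts = [], [], []
    for j in range(n_win):
        last = j == n_win - 1
        if last:
            sel = (dps >= los[j]) & (dps <= his[j])
        else:
            sel = (dps >= los[j]) & (dps < his[j])
        vals = values[sel]
        members.append(vals)
        counts.append(vals.size)
        means.append(vals.mean() if vals.size else np.nan)
    return DPWindowProfile(
        window_lo=los, window_hi=his, members=members,
        mean=np.asarray(means), n=np.asarray(counts),
    )


def window_ranksum_vs_first(profile: DPWindowProfile) -> np.ndarray:
    """Two-sided rank-sum p of every window against the first.

    The first window (DP 1.0-1.5) is the alert reference; its own
    entry is 1 by convention.  Windows with fewer than 2 members get
    a missing p (logged).  Identical member multisets give p = 1.
    """
    first = profile.members[0]
    if first.size == 0:
        raise ValueError("first DP window (alert reference) is empty")
    p = np.full(len(profile.members), np.nan)
    p[0] = 1.0
    for j in range(1, len(profile.members)):
        vals = profile.members[j]
        if vals.size < 2:
            logger.info("window %d has %d member(s); p left missing",
                        j, vals.size)
            continue
        pooled = np.concatenate([vals, first])
        if np.ptp(pooled) == 0:
            p[j] = 1.0
            continue
        p[j] = _stats.mannwhitneyu(vals, first,
                                   alternative="two-sided").pvalue
    profile.p_raw = p
    return p


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj_(i) = min_{j >= i} ( m * p_(j) / j )`` capped at 1, over the
    ``m`` non-missing entries; NaNs pass through untouched.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


def apply_window_fdr(profile: DPWindowProfile, alpha: float = 0.001
                     ) -> DPWindowProfile:
    """Convenience: rank-sum vs first window, then BH across windows."""
    window_ranksum_vs_first(profile)
    profile.p_adj = bh_fdr(profile.p_raw)
    profile.alpha = alpha
    return profile


def group_summarize(values, groups, subjects) -> pd.DataFrame:
    """Per-subject x per-group mean of (relative) connectivity values.

    Returns a DataFrame indexed by subject with one column per
    performance group (NaN where a subject has no trials in a
    group).  Downstream tests decide how to treat incomplete
    subjects: the repeated-measures ANOVA drops them (listwise),
    pairwise tests keep any subject with both cells of the contrast.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "group": np.asarray(groups, dtype=object),
        "subject": np.asarray(subjects),
    })
    if df.empty:
        raise ValueError("empty input")
    unknown = set(df["group"]) - set(GROUP_ORDER)
    if unknown:
        raise ValueError(f"unknown group label(s) {sorted(unknown)}")
    table = df.pivot_table(index="subject", columns="group", values="value",
                           aggfunc="mean")
    for g in GROUP_ORDER:
        if g not in table.columns:
            table[g] = np.nan
    return table[list(GROUP_ORDER)]


def rm_anova(table: pd.DataFrame) -> tuple[float, float]:
    """One-way repeated-measures ANOVA across the three groups.

    ``table`` is subjects x groups (from :func:`group_summarize`);
    subjects with any missing cell are dropped with a warning.
    F = MS_condition / MS_error with df (k-1), (k-1)(n-1), sphericity
    assumed.  Degenerate data (zero error variance) reports p = 1
    with a warning.
    """
    full = table.dropna(axis=0)
    dropped = len(table) - len(full)
    if dropped:
        logger.warning("rm_anova: %d subject(s) dropped for missing cells",
                       dropped)
    n, k = full.shape
    if n < 2 or k < 2:
        raise ValueError(
            "repeated-measures ANOVA needs >= 2 complete subjects and >= 2 "
            "conditions"
        )
    x = full.to_numpy()
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        if ss_cond <= 1e-300:
            logger.warning("rm_anova: degenerate data (no variance); p = 1")
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = (ss_cond / df_cond) / ms_err
    p = float(_stats.f.sf(f_stat, df_cond, df_err))
    return float(f_stat), p


def pairwise_signed_rank(table: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank tests between the three group pairs.

    Each contrast uses the subjects with both cells present (pairwise
    deletion).  All-zero differences give p = 1 by convention.  BH
    adjustment is applied across the three contrasts.
    """
    rows = []
    for a, b in PAIRWISE_CONTRASTS:
        sub = table[[a, b]].dropna(axis=0)
        if len(sub) < 2:
            raise ValueError(f"fewer than 2 paired subjects for ({a}, {b})")
        diff = sub[a].to_numpy() - sub[b].to_numpy()
        if np.all(diff == 0):
            p = 1.0
        else:
            p = float(_stats.wilcoxon(sub[a], sub[b],
                                      alternative="two-sided").pvalue)
        rows.append({"group_a": a, "group_b": b, "n_pairs": len(sub),
                     "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p_raw"].to_numpy())
    return out
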