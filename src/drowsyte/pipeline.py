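"""Configuration and end-to-end orchestration of the analysis chain.

``run_pipeline`` ties the stages together:

    simulate / ingest -> preprocess (filter, decimate, epoch)
    -> behavior (normalized RT, DP, groups)
    -> connectivity (per-trial TE and GC for every ordered pair)
    -> spectra (band powers, DP correlations)
    -> stats (baseline-relative values, DP-window profiles, FDR,
       group tests)

writing tidy CSV/JSON artifacts and a run manifest (config, seed,
versions) to an output directory.  Every stochastic stage consumes a
seed derived deterministically from the run seed and the stage name,
so a manifest suffices to reproduce every output bit-exactly.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, reference, stats, synth
from .preprocess import FilterSpec, bandpass_zero_phase, downsample, \
    extract_baseline_epochs
from .session import Epochs, Session, read_session, write_behavior, \
    write_epochs, write_session
from .synth import CouplingTruth, SessionConfig
from .te import DEFAULT_U_CANDIDATES_MS, EmbeddingSpec, cao_dimension, \
    ksg_te, ksg_te_epochs, select_delay, select_u

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed",
           "connectivity_per_trial", "resolve_embedding"]


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, defaulting to the study settings.

    Channels Fz/Cz/C3/C4/Pz/Oz; 1-50 Hz zero-phase FIR; 250 Hz
    analysis rate; KSG TE with k = 4, Theiler window 1, prediction
    time searched over 5-100 ms (5 ms = 1 sample at 250 Hz when
    fixed); DP windows of width 0.5 and step 0.1; group thresholds at
    DP 2 and 3; profile significance at FDR-adjusted p < 0.001 and
    group tests at 0.05 / 0.01.
    """

    channels: tuple[str, ...] = synth.DEFAULT_CHANNELS
    filter: FilterSpec = field(default_factory=FilterSpec)
    fs_target: float = 250.0
    embedding: EmbeddingSpec = field(default_factory=EmbeddingSpec)
    auto_embedding: bool = False      # Cao/autocorr selection per channel
    u_mode: str = "fixed"             # "fixed" uses embedding.u; "search"
    u_candidates_ms: tuple[float, ...] = DEFAULT_U_CANDIDATES_MS
    te_mode: str = "per_trial"        # or "pooled" within DP windows
    gc_order_max: int = 8
    window_width: float = 0.5
    window_step: float = 0.1
    dp_lo: float = 1.0
    dp_hi: float = 4.0
    alpha_profile: float = 0.001
    alpha_group: float = 0.05
    fdr_family: str = "per_pair"      # or "global"
    log_band_power: bool = True
    seed: int = 0
    simulate: dict = field(default_factory=dict)   # SessionConfig overrides
    truths: tuple = ()                              # CouplingTruth specs

    def __post_init__(self):
        if self.u_mode not in ("fixed", "search"):
            raise ValueError("u_mode must be 'fixed' or 'search'")
        if self.te_mode not in ("per_trial", "pooled"):
            raise ValueError("te_mode must be 'per_trial' or 'pooled'")
        if self.fdr_family not in ("per_pair", "global"):
            raise ValueError("fdr_family must be 'per_pair' or 'global'")
        missing = synth.REQUIRED_CHANNELS - set(self.channels)
        if missing:
            raise ValueError(f"unknown/missing channel labels: config must "
                             f"include {sorted(missing)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter"] = asdict(self.filter)
        d["embedding"] = asdict(self.embedding)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterSpec(**d["filter"])
        if "embedding" in d and isinstance(d["embedding"], dict):
            d["embedding"] = EmbeddingSpec(**d["embedding"])
        if "truths" in d:
            d["truths"] = tuple(
                t if isinstance(t, CouplingTruth) else CouplingTruth(**t)
                for t in d["truths"]
            )
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["truths"] = [asdict(t) if isinstance(t, CouplingTruth) else t
                       for t in self.truths]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{run_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def ordered_pairs(channels) -> list[tuple[str, str]]:
    """All directed (source, sink) pairs, no self-pairs."""
    return [(a, b) for a, b in itertools.permutations(channels, 2)]


def preprocess_session(session: Session, config: PipelineConfig) -> Epochs:
    """Filter, decimate to the analysis rate, and cut baseline epochs."""
    filtered = bandpass_zero_phase(session.data, session.fs, config.filter)
    factor_ok = session.fs / config.fs_target
    data = downsample(filtered, session.fs, config.fs_target)
    ds = Session(
        data=data, fs=config.fs_target, channels=list(session.channels),
        onsets=(session.onsets / factor_ok).astype(int), rts=session.rts,
        meta=dict(session.meta),
    )
    return extract_baseline_epochs(ds, epoch_len=1.0)


def resolve_embedding(epochs: Epochs, config: PipelineConfig,
                      channels: tuple[str, str]) -> EmbeddingSpec:
    """Embedding parameters for one (source, sink) pair.

    With ``auto_embedding`` the delay comes from the 1/e
    autocorrelation crossing and the dimensions from Cao's criterion,
    each evaluated on the channel's concatenated baseline epochs;
    otherwise the configured spec is used as-is.  The prediction time
    is either fixed or maximized over the millisecond candidate grid.
    """
    spec = config.embedding
    src, snk = channels
    if config.auto_embedding:
        x = epochs.channel(snk).ravel()
        y = epochs.channel(src).ravel()
        tau = max(select_delay(x), select_delay(y))
        n_samp = epochs.data.shape[2]
        tau = min(tau, max(1, (n_samp - 10) // 8))
        d = cao_dimension(x, tau, d_max=6)
        m = cao_dimension(y, tau, d_max=6)
        spec = spec.replace(d=d, m=m, tau=tau)
    if config.u_mode == "search":
        sub = min(epochs.n_trials, 40)  # subsample keeps the search cheap
        u, _ = select_u(epochs.channel(src)[:sub], epochs.channel(snk)[:sub],
                        spec, config.u_candidates_ms, epochs.fs)
        spec = spec.replace(u=u)
    return spec


def connectivity_per_trial(epochs: Epochs, config: PipelineConfig,
                           pairs=None, subject: str = "S01",
                           gc: bool = True, effective: bool = True,
                           seed: int | None = None) -> pd.DataFrame:
    """Per-trial TE (and GC) for the requested ordered pairs.

    Returns a tidy frame: subject, trial, source, sink, te_bits,
    te_eff_bits, gc_nats, u, d, m, tau.  Per-trial estimation on 1-s
    epochs is small-sample territory for a kNN estimator, and the
    bias depends on the signals' autocorrelation — which itself
    tracks vigilance.  With ``effective=True`` (default) each trial's
    estimate is therefore shuffle-corrected: the TE obtained from a
    random *other* trial's source (same marginals and
    autocorrelation, no coupling) is subtracted, giving the effective
    transfer entropy ``te_eff_bits`` used by the downstream
    statistics.
    """
    pairs = pairs or ordered_pairs(epochs.channels)
    if seed is None:
        seed = stage_seed(config.seed, "connectivity")
    rng = np.random.default_rng(seed)
    n_tr = epochs.n_trials
    rows = []
    for src, snk in pairs:
        spec = resolve_embedding(epochs, config, (src, snk))
        se = epochs.channel(src)
        ke = epochs.channel(snk)
        if effective and n_tr > 1:
            perm = (np.arange(n_tr) + 1 + rng.integers(0, n_tr - 1, n_tr)) \
                % n_tr  # random non-self source trial
        if gc:
            pooled_n = min(n_tr, 20)
            p_gc = reference.fit_var_order_bic(
                ke[:pooled_n].ravel(), se[:pooled_n].ravel(),
                p_max=config.gc_order_max,
            )
        for t in range(n_tr):
            te_val = ksg_te(se[t], ke[t], spec).value
            row = {
                "subject": subject, "trial": int(epochs.trial_index[t]),
                "source": src, "sink": snk, "te_bits": te_val,
                "u": spec.u, "d": spec.d, "m": spec.m, "tau": spec.tau,
            }
            if effective and n_tr > 1:
                null = ksg_te(se[perm[t]], ke[t], spec).value
                row["te_eff_bits"] = te_val - null
            if gc:
                row["gc_nats"] = reference.granger(ke[t], se[t], p_gc)
                row["gc_order"] = p_gc
            rows.append(row)
    return pd.DataFrame(rows)


def spectra_table(epochs: Epochs, dps: np.ndarray, config: PipelineConfig,
                  subject: str = "S01") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial band powers and their Pearson correlation with DP."""
    power_rows, corr_rows = [], []
    for ch in epochs.channels:
        powers = reference.band_powers_table(epochs.channel(ch), epochs.fs,
                                             log10=config.log_band_power)
        for band, vals in powers.items():
            for t, v in zip(epochs.trial_index, vals):
                power_rows.append({"subject": subject, "trial": int(t),
                                   "channel": ch, "band": band, "power": v})
            corr_rows.append({
                "subject": subject, "channel": ch, "band": band,
                "r": reference.band_dp_correlation(vals, dps),
            })
    return pd.DataFrame(power_rows), pd.DataFrame(corr_rows)


def profile_stats(conn: pd.DataFrame, beh: pd.DataFrame,
                  config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Baseline-relative values, DP-window profiles and group tests.

    ``conn`` is the tidy per-trial connectivity frame (one subject or
    many); ``beh`` maps (subject, trial) to DP.  Relative TE is
    computed within subject, then trials from all subjects are pooled
    for the window profiles.  Returns the augmented frame and a dict
    ``{(source, sink): {"profile": DPWindowProfile, "anova": (F, p),
    "pairwise": DataFrame}}``.
    """
    beh_idx = beh.set_index(["subject", "trial"]) if "subject" in beh \
        else beh.set_index("trial")
    conn = conn.copy()
    key = list(zip(conn["subject"], conn["trial"])) if "subject" in beh \
        else conn["trial"]
    conn["dp"] = beh_idx.loc[key, "dp"].to_numpy()
    conn["group"] = beh_idx.loc[key, "group"].to_numpy()

    value_col = "te_eff_bits" if "te_eff_bits" in conn.columns else "te_bits"
    rel = np.full(len(conn), np.nan)
    for (_subj, _src, _snk), idx in conn.groupby(
            ["subject", "source", "sink"]).groups.items():
        sub = conn.loc[idx]
        base = behavior.baseline_trial_indices(sub["dp"].to_numpy())
        rel[conn.index.get_indexer(idx)] = stats.relative_te(
            sub[value_col].to_numpy(), base)
    conn["relative_te"] = rel

    results = {}
    all_raw, slots = [], []
    for (src, snk), idx in conn.groupby(["source", "sink"]).groups.items():
        sub = conn.loc[idx]
        profile = stats.dp_windows(
            sub["dp"].to_numpy(), sub["relative_te"].to_numpy(),
            width=config.window_width, step=config.window_step,
            lo=config.dp_lo, hi=config.dp_hi,
        )
        stats.window_ranksum_vs_first(profile)
        if config.fdr_family == "per_pair":
            profile.p_adj = stats.bh_fdr(profile.p_raw)
        else:
            all_raw.append(profile.p_raw)
            slots.append(profile)
        profile.alpha = config.alpha_profile
        table = stats.group_summarize(sub["relative_te"], sub["group"],
                                      sub["subject"])
        anova = stats.rm_anova(table) if table.dropna().shape[0] >= 2 \
            else (np.nan, np.nan)
        pairwise = stats.pairwise_signed_rank(table) \
            if len(table) >= 2 else None
        results[(src, snk)] = {"profile": profile, "anova": anova,
                               "pairwise": pairwise, "group_table": table}
    if config.fdr_family == "global" and slots:
        flat = np.concatenate(all_raw)
        adj = stats.bh_fdr(flat)
        pos = 0
        for profile in slots:
            k = profile.p_raw.size
            profile.p_adj = adj[pos: pos + k]
            pos += k
    return conn, results


def run_pipeline(config: PipelineConfig, input_path: str | Path = "simulate",
                 outdir: str | Path = "pipeline_out",
                 pairs=None) -> dict:
    """Execute the full chain and write all artifacts.

    ``input_path`` is a serialized session (``.npy`` + sidecar) or
    the literal string ``"simulate"``.  Returns a dict of the main
    in-memory results; artifacts (CSVs, profile JSON, manifest) land
    in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, type(exc).__name__, str(exc)) from exc

    def _simulate():
        sim_kw = dict(config.simulate)
        sim_kw.setdefault("seed", stage_seed(config.seed, "simulate"))
        scfg = SessionConfig(channels=config.channels, **sim_kw)
        session, beh = synth.gen_session(scfg, config.truths)
        write_session(session, outdir / "session")
        return session, beh

    if str(input_path) == "simulate":
        session, beh = _stage("simulate", _simulate)
    else:
        session = _stage("ingest", lambda: read_session(input_path))
        beh = _stage("behavior",
                     lambda: behavior.behavior_table(session.rts))
    beh = beh.assign(subject="S01")
    write_behavior(beh, outdir / "behavior.csv")

    epochs = _stage("preprocess",
                    lambda: preprocess_session(session, config))
    write_epochs(epochs, outdir / "epochs")
    beh_kept = beh[beh["trial_index"].isin(epochs.trial_index + 1)]
    beh_kept = beh_kept.rename(columns={"trial_index": "trial"})
    beh_kept = beh_kept.assign(trial=beh_kept["trial"] - 1)

    conn = _stage("connectivity", lambda: connectivity_per_trial(
        epochs, config, pairs=pairs))
    conn.to_csv(outdir / "connectivity.csv", index=False)

    dps = beh_kept.set_index("trial").loc[epochs.trial_index, "dp"].to_numpy()
    powers, corr = _stage("spectra",
                          lambda: spectra_table(epochs, dps, config))
    powers.to_csv(outdir / "band_powers.csv", index=False)
    corr.to_csv(outdir / "band_dp_correlation.csv", index=False)

    conn_rel, results = _stage("stats",
                               lambda: profile_stats(conn, beh_kept, config))
    conn_rel.to_csv(outdir / "connectivity_relative.csv", index=False)
    profile_json = {
        f"{src}->{snk}": json.loads(
            res["profile"].to_frame().to_json(orient="records"))
        for (src, snk), res in results.items()
    }
    (outdir / "dp_profiles.json").write_text(json.dumps(profile_json))

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(_manifest_config(config))),
        "config_hash": hashlib.sha256(
            json.dumps(_manifest_config(config), sort_keys=True).encode()
        ).hexdigest(),
        "n_trials": int(epochs.n_trials),
        "n_pairs": int(conn[["source", "sink"]].drop_duplicates().shape[0]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"session": session, "behavior": beh, "epochs": epochs,
            "connectivity": conn_rel, "band_dp_correlation": corr,
            "results": results, "manifest": manifest}


def _manifest_config(config: PipelineConfig) -> dict:
    d = config.to_dict()
    d["truths"] = [asdict(t) if isinstance(t, CouplingTruth) else dict(t)
                   for t in config.truths]
    return d
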