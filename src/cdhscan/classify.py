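"""Control-anchored iterative k-means calling of drive haplotypes.

The caller never trusts a single clustering. Each round, experimental
samples are spiked in small numbers into a balanced panel of positive and
negative controls, the batch is min/max scaled and clustered with k-means
(k = 2), clusters are named by control purity (>= 80%), and the batch is
redrawn until every control lands in the cluster matching its known status.
125 independent rounds yield a consensus: a sample is called only when at
least 95% of its completed rounds agree, otherwise it is ambiguous.

High- and low-copy controls are clustered separately so that clustering
reflects presence/absence rather than copy number. Two stepwise pipelines
resolve haplotype confusions: Ab10 before K10L2 (the K10L2 features cannot
distinguish the two) and, for the B chromosome, high-copy controls before
low-copy controls (many-copy samples otherwise form their own cluster).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE, AMBIGUOUS, UNNAMED = "positive", "negative", "ambiguous", "unnamed"
_EPS = 1e-12


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the iterative k-means caller (defaults follow the published
    protocol; see docs/methods.md for rationale)."""

    k: int = 2
    purity_threshold: float = 0.80
    consensus_rounds: int = 125
    consensus_threshold: float = 0.95
    spike_fraction: float = 0.25  # 0.25 for Ab10/K10L2, 0.10 for B
    control_validation_rounds: int = 100
    control_groups: int = 3
    max_batch_retries: int = 50
    balance_tolerance: float = 0.20
    kmeans_restarts: int = 10
    kmeans_max_iter: int = 100
    min_round_fraction: float = 0.5
    separation_threshold: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.purity_threshold <= 1):
            raise ValueError("purity_threshold must be in (0, 1]")
        if not (0 < self.consensus_threshold <= 1):
            raise ValueError("consensus_threshold must be in (0, 1]")
        if not (0 < self.spike_fraction <= 1):
            raise ValueError("spike_fraction must be in (0, 1]")


@dataclass
class BatchResult:
    samples: list[str]
    labels: np.ndarray  # cluster id per sample
    cluster_names: tuple[str, str]  # POSITIVE / NEGATIVE / UNNAMED per cluster
    controls_correct: bool
    exp_calls: dict[str, str]  # experimental sample -> POSITIVE/NEGATIVE
    attempts: int = 1


# ---------------------------------------------------------------------------
# k = 2 k-means (k-means++ init, restarts vectorized, Lloyd iterations)
# ---------------------------------------------------------------------------

def kmeans_two(
    X: np.ndarray,
    rng: np.random.Generator,
    restarts: int = 10,
    max_iter: int = 100,
) -> np.ndarray:
    """Cluster rows of X into 2 groups; returns labels of the best restart.

    Tiny-problem Lloyd iteration with k-means++ seeding, all restarts
    advanced in lockstep. The batches this serves are at most a few dozen
    samples by a few dozen bins, so the whole solve is a handful of small
    dense operations.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2 or np.ptp(X, axis=0).max() == 0:
        return np.zeros(n, dtype=int)

    R = restarts
    i0 = rng.integers(0, n, size=R)
    c0 = X[i0]  # (R, f)
    d2 = ((X[None, :, :] - c0[:, None, :]) ** 2).sum(-1)  # (R, n)
    tot = d2.sum(axis=1)
    u = rng.random(R) * np.where(tot > 0, tot, 1.0)
    i1 = np.minimum((np.cumsum(d2, axis=1) < u[:, None]).sum(axis=1), n - 1)
    degenerate = tot == 0
    if degenerate.any():  # identical points under this seeding; any split works
        i1[degenerate] = (i0[degenerate] + 1) % n
    cent = np.stack([c0, X[i1]], axis=1)  # (R, 2, f)

    labels = None
    for _ in range(max_iter):
        d = ((X[None, None, :, :] - cent[:, :, None, :]) ** 2).sum(-1)  # (R, 2, n)
        new_labels = d.argmin(axis=1)  # (R, n)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in (0, 1):
            m = labels == k  # (R, n)
            cnt = m.sum(axis=1)
            sums = m.astype(float) @ X  # (R, f)
            ok = cnt > 0
            cent[ok, k] = sums[ok] / cnt[ok, None]
            if (~ok).any():
                # empty cluster: re-seed at the point farthest from the other centroid
                for r in np.flatnonzero(~ok):
                    far = ((X - cent[r, 1 - k]) ** 2).sum(-1).argmax()
                    cent[r, k] = X[far]

    d = ((X[None, None, :, :] - cent[:, :, None, :]) ** 2).sum(-1)
    inertia = d.min(axis=1).sum(axis=1)
    best = int(inertia.argmin())
    return labels[best].astype(int)


def _scale_rows_of_batch(X: np.ndarray) -> np.ndarray:
    """Min/max scale each feature (column of the samples-x-bins batch)."""
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    span[span == 0] = 1.0
    out = (X - lo) / span
    out[:, hi == lo] = 0.0
    return out


# ---------------------------------------------------------------------------
# Diagnostic-bin selection
# ---------------------------------------------------------------------------

def select_diagnostic_bins(
    index_mat: pd.DataFrame,
    positive_controls: list[str],
    negative_controls: list[str],
    separation_threshold: float = 0.5,
    override_bins: list[str] | None = None,
) -> list[str]:
    """Bins with a stark scaled-index difference between positive and
    negative controls.

    The tag index over the candidate bins is min/max scaled across the given
    controls; a bin is diagnostic when |mean(pos) - mean(neg)| exceeds the
    separation threshold. A user-supplied bin list overrides selection.
    """
    if override_bins is not None:
        missing = set(override_bins) - set(index_mat.index)
        if missing:
            raise ValueError(f"override bins absent from matrix: {sorted(missing)}")
        return list(override_bins)
    if len(positive_controls) < 2 or len(negative_controls) < 2:
        raise ValueError("need at least 2 positive and 2 negative controls")
    from .tagindex import minmax_scale

    scaled = minmax_scale(index_mat, list(positive_controls) + list(negative_controls))
    sep = (scaled[positive_controls].mean(axis=1) - scaled[negative_controls].mean(axis=1)).abs()
    chosen = list(sep.index[sep >= separation_threshold])
    if not chosen:
        raise ValueError(
            f"no bin separates the control classes (best separation {sep.max():.3f} "
            f"< threshold {separation_threshold})"
        )
    return chosen


# ---------------------------------------------------------------------------
# Batch clustering
# ---------------------------------------------------------------------------

class _FeatureView:
    """Numpy view of a bins-x-samples feature matrix for fast column gathers."""

    def __init__(self, features: pd.DataFrame):
        self.arr = np.ascontiguousarray(features.to_numpy(dtype=float).T)  # samples x bins
        self.pos = {s: i for i, s in enumerate(features.columns)}

    def rows(self, samples: list[str]) -> np.ndarray:
        return self.arr[[self.pos[s] for s in samples]]


def _balanced_control_sizes(n_pos: int, n_neg: int, tolerance: float) -> tuple[int, int]:
    small = min(n_pos, n_neg)
    cap = int(math.floor(small * (1 + tolerance)))
    return min(n_pos, cap), min(n_neg, cap)


def _draw_balanced(
    pos: list[str], neg: list[str], rng: np.random.Generator, tolerance: float
) -> tuple[list[str], list[str]]:
    kp, kn = _balanced_control_sizes(len(pos), len(neg), tolerance)
    p = list(rng.choice(pos, size=kp, replace=False)) if kp < len(pos) else list(pos)
    n = list(rng.choice(neg, size=kn, replace=False)) if kn < len(neg) else list(neg)
    return p, n


def _name_clusters(
    labels: np.ndarray, is_positive: np.ndarray, is_control: np.ndarray, purity: float
) -> tuple[str, str]:
    names = []
    for k in (0, 1):
        in_k = (labels == k) & is_control
        n_ctrl = int(in_k.sum())
        if n_ctrl == 0:
            names.append(UNNAMED)
            continue
        frac_pos = is_positive[in_k].mean()
        if frac_pos >= purity - _EPS:
            names.append(POSITIVE)
        elif (1 - frac_pos) >= purity - _EPS:
            names.append(NEGATIVE)
        else:
            names.append(UNNAMED)
    return tuple(names)


def _cluster_batch(
    view: _FeatureView,
    ctrl_pos: list[str],
    ctrl_neg: list[str],
    experimentals: list[str],
    config: PipelineConfig,
    rng: np.random.Generator,
) -> BatchResult:
    samples = list(ctrl_pos) + list(ctrl_neg) + list(experimentals)
    X = _scale_rows_of_batch(view.rows(samples))
    labels = kmeans_two(X, rng, config.kmeans_restarts, config.kmeans_max_iter)
    n_ctrl = len(ctrl_pos) + len(ctrl_neg)
    is_control = np.zeros(len(samples), dtype=bool)
    is_control[:n_ctrl] = True
    is_positive = np.zeros(len(samples), dtype=bool)
    is_positive[: len(ctrl_pos)] = True
    names = _name_clusters(labels, is_positive, is_control, config.purity_threshold)

    truth_names = np.where(is_positive[:n_ctrl], POSITIVE, NEGATIVE)
    ctrl_assigned = np.array([names[l] for l in labels[:n_ctrl]])
    controls_correct = bool((ctrl_assigned == truth_names).all())

    exp_calls = {}
    for s, l in zip(experimentals, labels[n_ctrl:]):
        if names[l] in (POSITIVE, NEGATIVE):
            exp_calls[s] = names[l]
    return BatchResult(samples, labels, names, controls_correct, exp_calls)


def run_batch(
    features: pd.DataFrame,
    positive_controls: list[str],
    negative_controls: list[str],
    experimentals: list[str],
    config: PipelineConfig,
    rng: np.random.Generator,
    view: _FeatureView | None = None,
) -> BatchResult:
    """One control-anchored batch, redrawn until all controls verify.

    A fresh balanced control draw is made on each attempt; after
    ``max_batch_retries`` failed verifications the batch is abandoned
    (``controls_correct`` False, no experimental calls).
    """
    if view is None:
        view = _FeatureView(features)
    kp, kn = _balanced_control_sizes(
        len(positive_controls), len(negative_controls), config.balance_tolerance
    )
    cap = max(1, int(math.floor(config.spike_fraction * (kp + kn))))
    if len(experimentals) > cap:
        raise ValueError(
            f"{len(experimentals)} experimental samples exceed the spike cap of {cap}"
        )
    last = None
    for attempt in range(1, config.max_batch_retries + 1):
        p, n = _draw_balanced(positive_controls, negative_controls, rng, config.balance_tolerance)
        res = _cluster_batch(view, p, n, list(experimentals), config, rng)
        res.attempts = attempt
        if res.controls_correct:
            return res
        last = res
    logger.warning(
        "batch abandoned after %d retries (%d experimental samples uncalled this round)",
        config.max_batch_retries,
        len(experimentals),
    )
    last.exp_calls = {}
    last.controls_correct = False
    return last


def batch_size_for(config: PipelineConfig, n_pos: int, n_neg: int) -> int:
    kp, kn = _balanced_control_sizes(n_pos, n_neg, config.balance_tolerance)
    return max(1, int(math.floor(config.spike_fraction * (kp + kn))))


# ---------------------------------------------------------------------------
# Consensus over rounds
# ---------------------------------------------------------------------------

def consensus_calls(
    features: pd.DataFrame,
    positive_controls: list[str],
    negative_controls: list[str],
    experimentals: list[str],
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Run the full round structure and return one CallRecord per sample.

    Each round partitions the experimental samples into spike-capped batches,
    each clustered with a fresh balanced control draw. The final call is the
    majority class iff its fraction of completed rounds reaches the consensus
    threshold; samples with under half their rounds completed are flagged.
    Columns: sample_id, call, consensus_fraction, rounds_used, n_positive,
    n_negative, low_rounds.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    experimentals = list(experimentals)
    if not experimentals:
        return pd.DataFrame(
            columns=[
                "sample_id", "call", "consensus_fraction",
                "rounds_used", "n_positive", "n_negative", "low_rounds",
            ]
        )
    view = _FeatureView(features)
    size = batch_size_for(config, len(positive_controls), len(negative_controls))
    tallies: dict[str, Counter] = {s: Counter() for s in experimentals}

    for _ in range(config.consensus_rounds):
        order = list(rng.permutation(experimentals))
        for i in range(0, len(order), size):
            chunk = order[i : i + size]
            res = run_batch(
                features, positive_controls, negative_controls, chunk, config, rng, view=view
            )
            for s, call in res.exp_calls.items():
                tallies[s][call] += 1

    rows = []
    for s in experimentals:
        t = tallies[s]
        completed = t[POSITIVE] + t[NEGATIVE]
        low = completed < config.min_round_fraction * config.consensus_rounds
        if completed == 0:
            call, frac = AMBIGUOUS, 0.0
        else:
            top, n_top = t.most_common(1)[0]
            frac = n_top / completed
            call = top if (frac >= config.consensus_threshold - _EPS and not low) else AMBIGUOUS
        rows.append(
            dict(
                sample_id=s, call=call, consensus_fraction=frac, rounds_used=completed,
                n_positive=t[POSITIVE], n_negative=t[NEGATIVE], low_rounds=low,
            )
        )
    return pd.DataFrame(rows)


def consensus_call_from_counts(
    n_positive: int, n_negative: int, config: PipelineConfig
) -> tuple[str, float]:
    """The consensus decision rule in isolation (majority >= threshold of
    completed rounds, else ambiguous)."""
    completed = n_positive + n_negative
    if completed == 0:
        return AMBIGUOUS, 0.0
    frac = max(n_positive, n_negative) / completed
    if frac >= config.consensus_threshold - _EPS:
        return (POSITIVE if n_positive >= n_negative else NEGATIVE), frac
    return AMBIGUOUS, frac


# ---------------------------------------------------------------------------
# Control validation
# ---------------------------------------------------------------------------

def control_validation(
    features: pd.DataFrame,
    positive_controls: list[str],
    negative_controls: list[str],
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Leave-truth-out check of the caller on controls alone.

    Controls are split into ``control_groups`` random groups (redrawn if a
    group misses a class); each group is clustered and named by purity; a
    control is correct when its named cluster matches its truth. Repeated
    ``control_validation_rounds`` times. Cohorts too small to give every
    group both classes are clustered as a single group.
    Returns per-control accuracy (sample_id, truth, n_correct, n_rounds,
    accuracy).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    pos, neg = list(positive_controls), list(negative_controls)
    if not pos or not neg:
        raise ValueError("both control classes must be non-empty")
    view = _FeatureView(features)
    all_ctrl = pos + neg
    is_pos = {s: (s in set(pos)) for s in all_ctrl}
    n_groups = config.control_groups
    if min(len(pos), len(neg)) < 2 * n_groups:
        # small-cohort fallback: without at least two controls of each class
        # per group, subsampling is unreliable — cluster all controls together
        n_groups = 1

    correct = Counter()
    for _ in range(config.control_validation_rounds):
        groups = _split_with_both_classes(all_ctrl, is_pos, n_groups, rng)
        for g in groups:
            gp = [s for s in g if is_pos[s]]
            gn = [s for s in g if not is_pos[s]]
            res = _cluster_batch(view, gp, gn, [], config, rng)
            truth = np.array([POSITIVE] * len(gp) + [NEGATIVE] * len(gn))
            assigned = np.array([res.cluster_names[l] for l in res.labels])
            for s, ok in zip(g, assigned == truth):
                correct[s] += int(ok)

    rows = [
        dict(
            sample_id=s,
            truth=POSITIVE if is_pos[s] else NEGATIVE,
            n_correct=correct[s],
            n_rounds=config.control_validation_rounds,
            accuracy=correct[s] / config.control_validation_rounds,
        )
        for s in all_ctrl
    ]
    return pd.DataFrame(rows)


def _split_with_both_classes(
    samples: list[str],
    is_pos: dict[str, bool],
    n_groups: int,
    rng: np.random.Generator,
    max_redraws: int = 200,
) -> list[list[str]]:
    if n_groups == 1:
        return [list(samples)]
    for _ in range(max_redraws):
        order = list(rng.permutation(samples))
        groups = [list(g) for g in np.array_split(np.array(order, dtype=object), n_groups)]
        if all(any(is_pos[s] for s in g) and any(not is_pos[s] for s in g) for g in groups):
            return groups
    raise RuntimeError("could not split controls into groups containing both classes")


# ---------------------------------------------------------------------------
# Stratified presence calls and the stepwise pipelines
# ---------------------------------------------------------------------------

def presence_calls_by_stratum(
    features: pd.DataFrame,
    controls_by_stratum: dict[str, list[str]],
    negative_controls: list[str],
    experimentals: list[str],
    config: PipelineConfig,
    rng: np.random.Generator,
    diagnostic_bins_by_stratum: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Consensus calls per copy stratum, combined by union of positives.

    High- and low-copy positive controls are clustered in separate runs so
    presence, not copy number, drives the clusters. A sample's final call is
    positive if any stratum's consensus is positive, negative if every
    stratum's consensus is negative, else ambiguous.
    """
    per_stratum: dict[str, pd.DataFrame] = {}
    for stratum, pos in controls_by_stratum.items():
        if not pos:
            continue
        feats = features
        if diagnostic_bins_by_stratum is not None:
            feats = features.loc[diagnostic_bins_by_stratum[stratum]]
        per_stratum[stratum] = consensus_calls(
            feats, pos, negative_controls, experimentals, config, rng
        ).set_index("sample_id")
    if not per_stratum:
        raise ValueError("no stratum has positive controls")

    rows = []
    for s in experimentals:
        calls = {st: df.loc[s, "call"] for st, df in per_stratum.items()}
        fracs = {st: df.loc[s, "consensus_fraction"] for st, df in per_stratum.items()}
        if POSITIVE in calls.values():
            call = POSITIVE
            frac = max(f for st, f in fracs.items() if calls[st] == POSITIVE)
        elif all(c == NEGATIVE for c in calls.values()):
            call = NEGATIVE
            frac = min(fracs.values())
        else:
            call, frac = AMBIGUOUS, max(fracs.values())
        rows.append(
            dict(sample_id=s, call=call, consensus_fraction=frac,
                 stratum_trace=";".join(f"{st}={c}" for st, c in sorted(calls.items())))
        )
    return pd.DataFrame(rows)


def chr10_pipeline(
    features_ab10: pd.DataFrame,
    features_k10l2: pd.DataFrame,
    ab10_controls: dict[str, list[str]],
    k10l2_controls: dict[str, list[str]],
    negative_controls: list[str],
    experimentals: list[str],
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
    ab10_bins_by_stratum: dict[str, list[str]] | None = None,
    k10l2_bins_by_stratum: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Stepwise chromosome-10 calling: Ab10 first, K10L2 on Ab10-negatives.

    The K10L2 features cannot distinguish Ab10 from K10L2 (the haplotypes
    share the TR-1/trkin region), so Ab10-positive samples are never
    forwarded and the order enforces mutual exclusivity; ambiguous Ab10
    samples are not forwarded either. Returns long-format calls with a
    ``cdh`` column (Ab10 rows for all samples, K10L2 rows for forwarded
    samples only).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    ab10 = presence_calls_by_stratum(
        features_ab10, ab10_controls, negative_controls, experimentals, config, rng,
        diagnostic_bins_by_stratum=ab10_bins_by_stratum,
    )
    ab10["cdh"] = "Ab10"
    forwarded = list(ab10.loc[ab10["call"] == NEGATIVE, "sample_id"])
    k10l2 = presence_calls_by_stratum(
        features_k10l2, k10l2_controls, negative_controls, forwarded, config, rng,
        diagnostic_bins_by_stratum=k10l2_bins_by_stratum,
    )
    k10l2["cdh"] = "K10L2"
    return pd.concat([ab10, k10l2], ignore_index=True)


def bchrom_pipeline(
    features_b: pd.DataFrame,
    b_controls: dict[str, list[str]],
    negative_controls: list[str],
    experimentals: list[str],
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
    bins_by_stratum: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Two-stage B-chromosome calling: high-copy controls first, then
    low-copy controls on the remainder; positives are the union.

    Samples with many B copies can otherwise form their own cluster, so the
    high-copy stage peels them off before low-copy detection. Uses the B
    spike fraction from ``config`` (0.10 by default at construction sites).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    def _feats(stratum: str) -> pd.DataFrame:
        if bins_by_stratum is None:
            return features_b
        return features_b.loc[bins_by_stratum[stratum]]

    stage1 = consensus_calls(
        _feats("high"), b_controls["high"], negative_controls, experimentals, config, rng
    ).set_index("sample_id")
    remaining = [s for s in experimentals if stage1.loc[s, "call"] != POSITIVE]
    stage2 = consensus_calls(
        _feats("low"), b_controls["low"], negative_controls, remaining, config, rng
    ).set_index("sample_id")

    rows = []
    for s in experimentals:
        if stage1.loc[s, "call"] == POSITIVE:
            call, frac, stage = POSITIVE, stage1.loc[s, "consensus_fraction"], "high"
        else:
            call, frac, stage = (
                stage2.loc[s, "call"], stage2.loc[s, "consensus_fraction"], "low"
            )
        rows.append(
            dict(sample_id=s, call=call, consensus_fraction=frac, cdh="B",
                 stratum_trace=f"stage={stage}")
        )
    return pd.DataFrame(rows)
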