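import numpy as np
import pandas as pd
import pytest

from cdhscan import classify
from cdhscan.classify import (
    AMBIGUOUS,
    NEGATIVE,
    POSITIVE,
    UNNAMED,
    PipelineConfig,
    batch_size_for,
    bchrom_pipeline,
    chr10_pipeline,
    consensus_call_from_counts,
    consensus_calls,
    control_validation,
    kmeans_two,
    run_batch,
    select_diagnostic_bins,
)


# ---------------------------------------------------------------------------
# k-means core, cross-checked against the sklearn implementation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_kmeans_partition_matches_sklearn(seed):
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(seed)
    n = 40
    X = np.vstack(
        [rng.normal(0, 0.3, (n // 2, 5)), rng.normal(2, 0.3, (n - n // 2, 5))]
    )
    ours = kmeans_two(X, np.random.default_rng(seed + 100))
    ref = KMeans(n_clusters=2, n_init=10, random_state=seed).fit_predict(X)
    same = (ours == ref).all() or (ours == 1 - ref).all()
    assert same, "partition disagrees with the sklearn reference"


def test_kmeans_degenerate_identical_points():
    X = np.ones((5, 3))
    labels = kmeans_two(X, np.random.default_rng(0))
    assert set(labels) <= {0, 1}


# ---------------------------------------------------------------------------
# Cluster naming and the consensus decision rule
# ---------------------------------------------------------------------------

def test_purity_naming_boundaries():
    # 5 positive + 1 negative control in a cluster: 5/6 >= 0.80 -> positive
    labels = np.zeros(6, dtype=int)
    is_pos = np.array([1, 1, 1, 1, 1, 0], dtype=bool)
    is_ctrl = np.ones(6, dtype=bool)
    names = classify._name_clusters(labels, is_pos, is_ctrl, 0.80)
    assert names[0] == POSITIVE

    # 3 positive + 2 negative: 0.60 < 0.80 -> unnamed
    is_pos = np.array([1, 1, 1, 0, 0], dtype=bool)
    names = classify._name_clusters(np.zeros(5, dtype=int), is_pos, np.ones(5, bool), 0.80)
    assert names[0] == UNNAMED

    # exactly 80% counts as named ("at least 80%")
    is_pos = np.array([1, 1, 1, 1, 0], dtype=bool)
    names = classify._name_clusters(np.zeros(5, dtype=int), is_pos, np.ones(5, bool), 0.80)
    assert names[0] == POSITIVE

    # experimental spikes never count toward purity
    is_ctrl = np.array([1, 1, 0, 0, 0], dtype=bool)
    is_pos = np.array([1, 1, 0, 0, 0], dtype=bool)  # spikes not positive controls
    names = classify._name_clusters(np.zeros(5, dtype=int), is_pos, is_ctrl, 0.80)
    assert names[0] == POSITIVE


def test_consensus_threshold_boundaries():
    cfg = PipelineConfig()
    call, frac = consensus_call_from_counts(120, 5, cfg)
    assert call == POSITIVE and frac == pytest.approx(0.96)
    call, frac = consensus_call_from_counts(117, 8, cfg)
    assert call == AMBIGUOUS and frac == pytest.approx(0.936)
    # 95% exactly qualifies
    call, _ = consensus_call_from_counts(19, 1, cfg)
    assert call == POSITIVE


def test_spike_cap():
    cfg = PipelineConfig(spike_fraction=0.25)
    # 50+50 balanced controls -> cap 25
    assert batch_size_for(cfg, 50, 50) == 25
    cfg_b = PipelineConfig(spike_fraction=0.10)
    assert batch_size_for(cfg_b, 50, 50) == 10


def test_run_batch_rejects_oversized_spike(prepared_panel):
    strata = prepared_panel["strata"]["Ab10"]
    neg = prepared_panel["negatives"]
    bins = prepared_panel["diag"]["Ab10"]["low"]
    feats = prepared_panel["tim"].index.loc[bins]
    cfg = PipelineConfig(spike_fraction=0.25)
    cap = batch_size_for(cfg, len(strata["low"]), len(neg))
    too_many = (strata["low"] + neg)[: cap + 1]  # any sample ids work as "spikes"
    with pytest.raises(ValueError, match="spike cap"):
        run_batch(feats, strata["low"], neg, too_many, cfg, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Diagnostic-bin selection
# ---------------------------------------------------------------------------

def test_select_diagnostic_bins_rule():
    # bin b1 separates (0.9 vs 0.05 scaled), shared bin b2 does not
    mat = pd.DataFrame(
        {
            "p1": [10.0, 8.0],
            "p2": [9.0, 7.5],
            "n1": [0.5, 7.0],
            "n2": [0.6, 8.0],
        },
        index=["b1", "b2"],
    )
    bins = select_diagnostic_bins(mat, ["p1", "p2"], ["n1", "n2"], 0.5)
    assert bins == ["b1"]


def test_select_diagnostic_bins_override_and_failure():
    # after scaling the class means coincide: no diagnostic bin exists
    mat = pd.DataFrame(
        {"p1": [0.50], "p2": [0.60], "n1": [0.45], "n2": [0.65]}, index=["b1"]
    )
    with pytest.raises(ValueError, match="best separation"):
        select_diagnostic_bins(mat, ["p1", "p2"], ["n1", "n2"], 0.5)
    assert select_diagnostic_bins(
        mat, ["p1", "p2"], ["n1", "n2"], 0.5, override_bins=["b1"]
    ) == ["b1"]


# ---------------------------------------------------------------------------
# Control validation
# ---------------------------------------------------------------------------

def test_control_validation_perfect_on_clean_controls(prepared_panel):
    cfg = PipelineConfig(rng_seed=1, control_validation_rounds=50)
    rng = np.random.default_rng(1)
    for cdh in ("Ab10", "K10L2", "B"):
        for stratum, pos in prepared_panel["strata"][cdh].items():
            feats = prepared_panel["tim"].index.loc[prepared_panel["diag"][cdh][stratum]]
            res = control_validation(feats, pos, prepared_panel["negatives"], cfg, rng)
            assert (res["accuracy"] == 1.0).all(), f"{cdh}/{stratum} below 100%"


def test_control_validation_chance_when_labels_carry_no_signal(prepared_panel):
    """Relabeling half the negative controls as positive leaves nothing to
    discriminate: accuracy collapses toward chance."""
    neg = prepared_panel["negatives"]
    feats = prepared_panel["tim"].index.loc[
        prepared_panel["diag"]["Ab10"]["low"], neg
    ]
    fake_pos, fake_neg = neg[: len(neg) // 2], neg[len(neg) // 2 :]
    cfg = PipelineConfig(rng_seed=2, control_validation_rounds=60)
    res = control_validation(feats, fake_pos, fake_neg, cfg, np.random.default_rng(2))
    assert 0.15 < res["accuracy"].mean() < 0.85


def test_control_validation_single_group_fallback(prepared_panel):
    pos = prepared_panel["strata"]["Ab10"]["low"][:3]
    neg = prepared_panel["negatives"][:2]
    feats = prepared_panel["tim"].index.loc[prepared_panel["diag"]["Ab10"]["low"]]
    cfg = PipelineConfig(rng_seed=3, control_validation_rounds=20, control_groups=3)
    res = control_validation(feats, pos, neg, cfg, np.random.default_rng(3))
    assert len(res) == 5  # runs despite too few controls for 3 groups
    assert (res["n_rounds"] == 20).all()


# ---------------------------------------------------------------------------
# Consensus calling and the stepwise pipelines (synthetic truth recovery)
# ---------------------------------------------------------------------------

def _run_pipelines(ps, seed=0):
    from dataclasses import replace

    cfg = ps["config"]
    rng = np.random.default_rng(seed)
    calls = chr10_pipeline(
        ps["tim"].index,
        ps["tim"].index,
        ps["strata"]["Ab10"],
        ps["strata"]["K10L2"],
        ps["negatives"],
        ps["experimentals"],
        replace(cfg, spike_fraction=0.25),
        rng,
        ab10_bins_by_stratum=ps["diag"]["Ab10"],
        k10l2_bins_by_stratum=ps["diag"]["K10L2"],
    )
    b_calls = bchrom_pipeline(
        ps["tim"].index,
        ps["strata"]["B"],
        ps["negatives"],
        ps["experimentals"],
        replace(cfg, spike_fraction=0.10),
        rng,
        bins_by_stratum=ps["diag"]["B"],
    )
    return calls, b_calls


@pytest.fixture(scope="module")
def pipeline_calls(prepared_study):
    return _run_pipelines(prepared_study)


def test_stepwise_truth_recovery(prepared_study, pipeline_calls):
    calls, b_calls = pipeline_calls
    truth = prepared_study["truth"]
    ab10 = calls[calls["cdh"] == "Ab10"].set_index("sample_id")
    k10l2 = calls[calls["cdh"] == "K10L2"].set_index("sample_id")
    b = b_calls.set_index("sample_id")
    for s in prepared_study["experimentals"]:
        t = truth.loc[s]
        assert ab10.loc[s, "call"] == (POSITIVE if t["ab10_copies"] > 0 else NEGATIVE)
        assert b.loc[s, "call"] == (POSITIVE if t["b_copies"] > 0 else NEGATIVE)
        if t["ab10_copies"] > 0:
            assert s not in k10l2.index  # Ab10 positives never reach K10L2
        else:
            assert k10l2.loc[s, "call"] == (
                POSITIVE if t["k10l2_copies"] > 0 else NEGATIVE
            )


def test_no_sample_positive_for_both_chr10_haplotypes(pipeline_calls):
    calls, _ = pipeline_calls
    pos = calls[calls["call"] == POSITIVE]
    both = pos.groupby("sample_id")["cdh"].nunique()
    assert (both <= 1).all()


def test_b_two_stage_routing(layout):
    """High-copy samples resolve in the high-copy stage; 1-copy samples fall
    through to the low-copy stage; 0-copy samples end negative."""
    from dataclasses import replace as drep

    from cdhscan import synth
    from cdhscan.cli import control_sets, diagnostic_bins_per_stratum, prepare_features

    spec = synth.preset("strong")
    rng = np.random.default_rng(31)
    universe = synth.realize_tags(layout, rng)
    panel_tbt, panel_meta, _ = synth.make_control_panel(layout, spec, rng, universe)
    rows = [
        dict(sample_id=f"X{c}_{i}", cdh="B" if c else "none", ab10_type=pd.NA,
             ab10_copies=0, k10l2_copies=0, b_copies=c, blank=False)
        for c in (0, 1, 8)
        for i in range(4)
    ]
    truth = pd.DataFrame(rows)
    exp_tbt = synth.simulate_counts(universe, truth, spec, rng)
    from cdhscan.ingest import TagByTaxa

    tbt = TagByTaxa(universe.tags.copy(), pd.concat([panel_tbt.counts, exp_tbt.counts], axis=1))
    exp_meta = pd.DataFrame(
        {"sample_id": truth["sample_id"], "role": "experimental", "control_cdh": pd.NA,
         "copy_stratum": pd.NA, "ab10_type": pd.NA, "replicate_group": pd.NA}
    )
    meta = pd.concat([panel_meta, exp_meta], ignore_index=True)

    cfg = PipelineConfig(rng_seed=31, consensus_rounds=25, spike_fraction=0.10)
    _, meta2, _, tim, _ = prepare_features(tbt, meta, layout.region_lengths, cfg)
    strata, neg = control_sets(meta2, "B")
    diag = diagnostic_bins_per_stratum(tim, "chrB", strata, neg, cfg)
    b = bchrom_pipeline(
        tim.index, strata, neg, list(truth["sample_id"]), cfg,
        np.random.default_rng(31), bins_by_stratum=diag,
    ).set_index("sample_id")

    t = truth.set_index("sample_id")["b_copies"]
    assert all(b.loc[s, "call"] == POSITIVE for s in t.index[t > 0])
    assert all(b.loc[s, "call"] == NEGATIVE for s in t.index[t == 0])
    # every 1-copy sample is missed by the high-copy stage and rescued by the
    # low-copy stage
    assert all(b.loc[s, "stratum_trace"] == "stage=low" for s in t.index[t == 1])
    assert all(b.loc[s, "stratum_trace"] == "stage=high" for s in t.index[t == 8])


def test_consensus_is_deterministic_under_fixed_seed(prepared_study):
    ps = prepared_study
    feats = ps["tim"].index.loc[ps["diag"]["Ab10"]["low"]]
    exps = ps["experimentals"][:8]
    args = (feats, ps["strata"]["Ab10"]["low"], ps["negatives"], exps)
    cfg = PipelineConfig(rng_seed=7, consensus_rounds=15)
    r1 = consensus_calls(*args, cfg, np.random.default_rng(7))
    r2 = consensus_calls(*args, cfg, np.random.default_rng(7))
    pd.testing.assert_frame_equal(r1, r2)


def test_ambiguity_rises_as_signal_shrinks(layout):
    """Effect-size sensitivity: weakening the haplotype-specific signal can
    only push samples from confident calls toward ambiguity."""
    from dataclasses import replace as drep

    from cdhscan import synth
    from cdhscan.cli import control_sets, diagnostic_bins_per_stratum, prepare_features

    rates = []
    for signal in (1.0, 0.12, 0.04):
        spec = drep(
            synth.preset("strong"), signal=signal, n_samples=24, freq_ab10=0.5,
            freq_k10l2=0.0, freq_b=0.0,
        )
        tbt, meta, truth = synth.simulate_study(layout, spec, seed=21)
        cfg = PipelineConfig(rng_seed=21, consensus_rounds=20, max_batch_retries=10)
        tbt2, meta2, _, tim, _ = prepare_features(tbt, meta, layout.region_lengths, cfg)
        strata, neg = control_sets(meta2, "Ab10")
        try:
            diag = diagnostic_bins_per_stratum(tim, "ab10_hap", strata, neg, cfg)
            bins = diag["low"]
        except ValueError:
            rates.append(1.0)  # no separating bin at all: nothing is callable
            continue
        exps = [s for s in meta2.loc[meta2["role"] == "experimental", "sample_id"]
                if s in tbt2.counts.columns]
        res = consensus_calls(
            tim.index.loc[bins], strata["low"], neg, exps, cfg,
            np.random.default_rng(21),
        )
        rates.append((res["call"] == AMBIGUOUS).mean())
    assert rates[0] <= 0.05, f"strong signal should be nearly fully callable: {rates}"
    assert rates[0] <= rates[1] + 1e-9 and rates[1] <= rates[2] + 1e-9, rates
    assert rates[2] > 0.5, f"near-background signal should be mostly ambiguous: {rates}"
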