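import numpy as np
import pandas as pd
import pytest

from cdhscan import synth
from cdhscan.classify import PipelineConfig
from cdhscan.cli import control_sets, diagnostic_bins_per_stratum, prepare_features

CDH_REGIONS = {"Ab10": "ab10_hap", "K10L2": "k10l2_hap", "B": "chrB"}


@pytest.fixture(scope="session")
def layout():
    return synth.SimLayout()


@pytest.fixture(scope="session")
def panel(layout):
    """Default control panel (paper-mirroring class counts, strong signal)."""
    spec = synth.preset("strong")
    tbt, meta, truth = synth.make_control_panel(layout, spec, np.random.default_rng(11))
    return tbt, meta, truth


@pytest.fixture(scope="session")
def prepared_panel(layout, panel):
    """Panel run through the ingest front end, plus per-stratum diagnostic bins."""
    tbt, meta, _ = panel
    cfg = PipelineConfig(rng_seed=11)
    tbt2, meta2, depth, tim, report = prepare_features(
        tbt, meta, layout.region_lengths, cfg
    )
    strata, diag = {}, {}
    negatives = []
    for cdh, region in CDH_REGIONS.items():
        strata[cdh], negatives = control_sets(meta2, cdh)
        diag[cdh] = diagnostic_bins_per_stratum(tim, region, strata[cdh], negatives, cfg)
    return {
        "tbt": tbt2,
        "meta": meta2,
        "depth": depth,
        "tim": tim,
        "strata": strata,
        "negatives": negatives,
        "diag": diag,
        "config": cfg,
    }


@pytest.fixture(scope="session")
def small_study(layout):
    """Control panel + 40-sample experimental cohort on one tag universe."""
    from dataclasses import replace

    spec = replace(
        synth.preset("strong"),
        n_samples=40,
        freq_ab10=0.15,
        freq_k10l2=0.15,
        freq_b=0.25,
    )
    tbt, meta, truth = synth.simulate_study(layout, spec, seed=12)
    return tbt, meta, truth


@pytest.fixture(scope="session")
def prepared_study(layout, small_study):
    tbt, meta, truth = small_study
    cfg = PipelineConfig(rng_seed=12, consensus_rounds=25)
    tbt2, meta2, depth, tim, _ = prepare_features(tbt, meta, layout.region_lengths, cfg)
    strata, diag = {}, {}
    negatives = []
    for cdh, region in CDH_REGIONS.items():
        strata[cdh], negatives = control_sets(meta2, cdh)
        diag[cdh] = diagnostic_bins_per_stratum(tim, region, strata[cdh], negatives, cfg)
    exps = [
        s
        for s in meta2.loc[meta2["role"] == "experimental", "sample_id"]
        if s in tbt2.counts.columns
    ]
    return {
        "tbt": tbt2,
        "meta": meta2,
        "tim": tim,
        "strata": strata,
        "negatives": negatives,
        "diag": diag,
        "config": cfg,
        "experimentals": exps,
        "truth": truth.set_index("sample_id"),
    }


@pytest.fixture()
def tiny_tbt():
    """Hand-built 3-tag, 2-sample table."""
    from cdhscan.ingest import TagByTaxa

    tags = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [100, 2000, 50],
            "end": [164, 2064, 114],
            "mapq": [60, 25, 19],
        },
        index=pd.Index(["t1", "t2", "t3"], name="tag_id"),
    )
    counts = pd.DataFrame(
        [[5, 0], [2, 1], [0, 3]], index=tags.index, columns=["A", "B"]
    )
    return TagByTaxa(tags, counts)
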