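"""Copy-number estimation from the relative tag index.

Drive-haplotype coverage is normalized to a single-copy baseline: the mean
tag index across 1 Mb bins of concatenated single-copy core-gene sequence
(gene space, not genomic coordinates). The relative index — mean diagnostic
haplotype index over mean core-gene index — is dimensionless, cancels
library size, and increases with copy number but is not an integer: much of
the haplotype sequence is repetitive or poorly conserved, so fewer tags
align to it than to a same-size stretch of gene space. One-copy increments
are calibrated from the 1- and 2-copy control medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tagindex import BIN_WIDTH, BinGrid, TagIndexMatrix, tag_index

logger = logging.getLogger(__name__)


@dataclass
class GeneSpaceBins:
    """1 Mb bins over concatenated single-copy core-gene sequence.

    ``genes`` holds the source intervals (chrom, start, end) with their
    cumulative offset in gene space; ``total_length`` is the summed gene
    length.
    """

    genes: pd.DataFrame  # chrom, start, end, offset
    total_length: int

    @property
    def n_bins(self) -> int:
        return -(-self.total_length // BIN_WIDTH)

    @property
    def grid(self) -> BinGrid:
        return BinGrid("gene_space", self.total_length)


def build_gene_space_bins(gene_intervals: pd.DataFrame) -> GeneSpaceBins:
    """Lay non-overlapping core-gene intervals end to end into gene space.

    ``gene_intervals`` needs chrom/start/end columns; overlapping intervals
    on the same chromosome are an error.
    """
    g = gene_intervals[["chrom", "start", "end"]].copy()
    g = g.sort_values(["chrom", "start"]).reset_index(drop=True)
    same = g["chrom"] == g["chrom"].shift()
    if (same & (g["start"] < g["end"].shift())).any():
        raise ValueError("overlapping core-gene intervals")
    lengths = (g["end"] - g["start"]).to_numpy()
    g["offset"] = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return GeneSpaceBins(g, int(lengths.sum()))


def assign_tags_to_gene_space(tags: pd.DataFrame, gsb: GeneSpaceBins) -> pd.Series:
    """Map tags inside a core gene to their gene-space bin.

    A tag belongs to a gene when its start lies within the interval; its
    gene-space position is offset + (start - gene start). Tags outside every
    gene are excluded from the baseline.
    """
    out = {}
    for chrom, genes in gsb.genes.groupby("chrom", sort=False):
        t = tags[tags["chrom"] == chrom]
        if t.empty:
            continue
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        offs = genes["offset"].to_numpy()
        pos = t["start"].to_numpy()
        gi = np.searchsorted(starts, pos, side="right") - 1
        ok = (gi >= 0) & (pos < ends[np.clip(gi, 0, None)])
        gpos = offs[gi[ok]] + (pos[ok] - starts[gi[ok]])
        for tid, p in zip(t.index[ok], gpos):
            out[tid] = int(p // BIN_WIDTH)
    return pd.Series(out, dtype=int)


def gene_space_tag_index(
    depth: pd.DataFrame, tags: pd.DataFrame, gsb: GeneSpaceBins
) -> TagIndexMatrix:
    return tag_index(depth, assign_tags_to_gene_space(tags, gsb), gsb.grid)


def baseline(gene_bin_index: pd.DataFrame) -> pd.Series:
    """Per-sample mean tag index across all gene-space bins.

    All-zero samples get a 0 baseline (flagged by a warning); their relative
    index is undefined downstream.
    """
    b = gene_bin_index.mean(axis=0)
    dead = b[b == 0]
    if len(dead):
        logger.warning("samples with zero core-gene baseline: %s", list(dead.index))
    return b


def relative_index(cdh_bin_index: pd.DataFrame, base: pd.Series) -> pd.Series:
    """Mean diagnostic-bin tag index divided by the core-gene baseline.

    Samples with a zero baseline come back NaN.
    """
    num = cdh_bin_index.mean(axis=0)
    base = base.reindex(num.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = num / base.replace(0, np.nan)
    return val


@dataclass(frozen=True)
class Calibration:
    delta: float  # relative-index step per copy
    offset: float  # relative index at zero copies


def calibrate(
    values: pd.Series, one_copy: list[str], two_copy: list[str]
) -> Calibration:
    """Two-point median calibration of the copies-per-relative-index step.

    Medians are used because control strata are small. Fails when the
    two-copy median does not exceed the one-copy median.
    """
    m1 = float(values[list(one_copy)].median())
    m2 = float(values[list(two_copy)].median())
    delta = m2 - m1
    if delta <= 0:
        raise ValueError(
            f"calibration failure: two-copy median {m2:.4f} <= one-copy median {m1:.4f}"
        )
    return Calibration(delta=delta, offset=m1 - delta)


def estimate_copies(
    values: pd.Series, cal: Calibration, max_copies: int | None = None
) -> pd.Series:
    """Round relative indices to the nearest one-copy increment.

    Rounding is to nearest with ties-to-even; estimates are clipped at 0 and
    optionally at ``max_copies`` (e.g. 2 for Ab10/K10L2, uncapped for B).
    NaN values stay NaN.
    """
    raw = (values - cal.offset) / cal.delta
    est = np.round(raw).clip(lower=0)
    if max_copies is not None:
        est = est.clip(upper=max_copies)
    return est


def calibrate_and_estimate(
    values: pd.Series,
    one_copy: list[str],
    two_copy: list[str],
    max_copies: int | None = None,
) -> tuple[pd.Series, Calibration]:
    cal = calibrate(values, one_copy, two_copy)
    return estimate_copies(values, cal, max_copies), cal
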