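"""Reading and filtering of tag-by-taxa tables.

GBS reads collapse into 64 bp "tags" mapped to discrete genomic tag sites.
The input to the pipeline is a table of read counts per tag site per sample,
a BED file of tag coordinates (score column = BWA mapping quality) and a
sample metadata sheet distinguishing blanks (no-DNA lanes), controls with
known drive-haplotype status, and experimental samples.

Filtering follows the published protocol: technical replicates are summed per
biological individual, reads-per-million normalizes library size, the minimum
blank missingness minus 0.001 sets the sample cutoff, and tags with mapping
quality below 20 are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = [
    "sample_id",
    "role",
    "control_cdh",
    "copy_stratum",
    "ab10_type",
    "replicate_group",
]

TAG_COLUMNS = ["chrom", "start", "end", "mapq"]


@dataclass
class TagByTaxa:
    """A tag-by-taxa count table.

    Attributes
    ----------
    tags : pd.DataFrame
        Indexed by tag_id with columns chrom, start, end, mapq.
        Coordinates are 0-based half-open (BED convention).
    counts : pd.DataFrame
        Integer read counts, rows aligned to ``tags``, one column per sample.
    """

    tags: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.tags.index.equals(self.counts.index):
            raise ValueError("tags and counts are not aligned on tag_id")
        if self.tags.index.has_duplicates:
            raise ValueError("duplicate tag_id in table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        if not (self.tags["start"] < self.tags["end"]).all():
            raise ValueError("tag with start >= end")
        if (self.tags["mapq"] < 0).any():
            raise ValueError("negative mapping quality")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def copy(self) -> "TagByTaxa":
        return TagByTaxa(self.tags.copy(), self.counts.copy())


def read_tag_table(
    counts_path, coords_path, meta_path
) -> tuple[TagByTaxa, pd.DataFrame]:
    """Read counts TSV + tag BED + metadata TSV into joined structures.

    The counts table has tag_id as its first column; the BED file carries
    tag_id in the name column and MAPQ in the score column. Tags present in
    the counts table but absent from the BED are dropped with a warning.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in counts table")

    bed = pd.read_csv(
        coords_path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(5),
        names=["chrom", "start", "end", "tag_id", "mapq"],
        dtype={"chrom": str, "tag_id": str},
    )
    tags = bed.set_index("tag_id")[TAG_COLUMNS]
    if tags.index.has_duplicates:
        raise ValueError("duplicate tag_id in coordinates BED")

    missing = counts.index.difference(tags.index)
    if len(missing):
        logger.warning(
            "%d tags in counts table have no coordinates and were dropped", len(missing)
        )
    keep = counts.index.intersection(tags.index)
    counts = counts.loc[keep]
    tags = tags.loc[keep]

    meta = read_sample_meta(meta_path)
    unknown = set(meta["sample_id"]) - set(counts.columns)
    if unknown:
        raise ValueError(f"metadata lists samples absent from counts table: {sorted(unknown)}")
    unlisted = set(counts.columns) - set(meta["sample_id"])
    if unlisted:
        raise ValueError(f"samples in counts table missing from metadata: {sorted(unlisted)}")

    return TagByTaxa(tags, counts), meta


def read_sample_meta(meta_path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    for col in META_COLUMNS:
        if col not in meta.columns:
            meta[col] = pd.NA
    meta = meta[META_COLUMNS]
    validate_meta(meta)
    return meta


def validate_meta(meta: pd.DataFrame) -> None:
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    bad_role = ~meta["role"].isin(["blank", "control", "experimental"])
    if bad_role.any():
        raise ValueError(f"unknown role(s): {meta.loc[bad_role, 'role'].unique()}")
    ctrl = meta["role"] == "control"
    if (ctrl & meta["control_cdh"].isna()).any():
        raise ValueError("control sample without control_cdh")
    if ((meta["role"] == "blank") & meta["control_cdh"].notna()).any():
        raise ValueError("blank sample with a control_cdh label")


def missingness(tbt: TagByTaxa) -> pd.Series:
    """Per-sample fraction of tag sites with zero reads."""
    return (tbt.counts == 0).mean(axis=0)


def merge_technical_replicates(
    tbt: TagByTaxa, meta: pd.DataFrame
) -> tuple[TagByTaxa, pd.DataFrame]:
    """Sum tag counts over technical replicates of each biological individual.

    Samples sharing a ``replicate_group`` collapse to one column named after
    the group; samples without a group pass through unchanged. Returns the
    merged table and metadata updated to one row per individual.
    """
    meta = meta.set_index("sample_id")
    grouped = meta.loc[meta["replicate_group"].notna(), "replicate_group"]
    present = grouped.index.intersection(tbt.counts.columns)
    absent_groups = set(grouped.unique()) - set(grouped.loc[present].unique())
    if absent_groups:
        raise ValueError(
            f"replicate group(s) with no samples in the count table: {sorted(absent_groups)}"
        )

    cols = {}
    new_meta_rows = []
    done_groups: set[str] = set()
    for s in tbt.counts.columns:
        if s in grouped.index:
            g = grouped[s]
            if g in done_groups:
                continue
            members = grouped.index[(grouped == g)].intersection(tbt.counts.columns)
            cols[g] = tbt.counts[list(members)].sum(axis=1)
            row = meta.loc[members[0]].copy()
            row["replicate_group"] = g
            row.name = g
            new_meta_rows.append(row)
            done_groups.add(g)
        else:
            cols[s] = tbt.counts[s]
            new_meta_rows.append(meta.loc[s])
    merged = pd.DataFrame(cols)
    new_meta = pd.DataFrame(new_meta_rows)
    new_meta.index.name = "sample_id"
    return TagByTaxa(tbt.tags, merged), new_meta.reset_index()


def rpm_normalize(tbt: TagByTaxa) -> pd.DataFrame:
    """Reads-per-million per tag per sample.

    A sample with zero total reads stays all-zero (and is logged); every
    other column sums to 1e6.
    """
    totals = tbt.counts.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        logger.warning("samples with zero reads kept all-zero: %s", list(totals.index[zero]))
    safe = totals.replace(0, 1.0)
    return tbt.counts.div(safe, axis=1) * 1e6


def blank_missingness_cutoff(
    tbt: TagByTaxa, meta: pd.DataFrame, fallback: float | None = None
) -> float:
    """Missingness cutoff = min blank missingness - 0.001.

    Blanks are no-DNA lanes; their missingness measures sequencing
    background. Without blanks an explicit ``fallback`` cutoff must be
    supplied (its use is logged).
    """
    blanks = meta.loc[meta["role"] == "blank", "sample_id"]
    blanks = [b for b in blanks if b in tbt.counts.columns]
    if not blanks:
        if fallback is not None:
            logger.info("no blank samples; using supplied cutoff %.4f", fallback)
            return float(fallback)
        raise ValueError(
            "no blank samples in the dataset: supply an explicit missingness cutoff"
        )
    m = missingness(tbt)[blanks]
    return float(m.min() - 0.001)


def filter_samples(
    tbt: TagByTaxa, cutoff: float
) -> tuple[TagByTaxa, pd.DataFrame]:
    """Drop samples with *more* missing data than the cutoff (strict >).

    Returns the filtered table and a report (sample, missingness, kept).
    """
    m = missingness(tbt)
    keep = m <= cutoff
    report = pd.DataFrame(
        {"sample_id": m.index, "missingness": m.values, "kept": keep.values}
    )
    if not keep.any():
        raise ValueError("missingness filter removed every sample")
    removed = list(m.index[~keep])
    if removed:
        logger.info("missingness filter removed %d samples: %s", len(removed), removed)
    return TagByTaxa(tbt.tags, tbt.counts.loc[:, keep.values]), report


def filter_tags_by_mapq(tbt: TagByTaxa, min_mapq: int = 20) -> TagByTaxa:
    """Drop tags with BWA mapping quality below ``min_mapq``."""
    keep = tbt.tags["mapq"] >= min_mapq
    return TagByTaxa(tbt.tags.loc[keep], tbt.counts.loc[keep.values])


def comparability_report(tbt: TagByTaxa, meta: pd.DataFrame, by: str = "role") -> pd.DataFrame:
    """Per-group missingness summary, logged for dataset comparability.

    Informational only: it echoes the check that all data sources are
    affected similarly by the filters, and never gates execution.
    """
    m = missingness(tbt)
    meta_idx = meta.set_index("sample_id")
    groups = meta_idx.reindex(m.index)[by]
    rep = m.groupby(groups).agg(["count", "mean", "min", "max"])
    logger.info("missingness by %s:\n%s", by, rep.to_string())
    return rep
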