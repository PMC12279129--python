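"""The binned tag index: sqrt(c) + d over non-overlapping 1 Mb windows.

Per sample and per bin, c is the number of tag sites observed (read depth
> 0) in that sample and d is the summed reads-per-million depth of the
bin's tags. c is sample-varying by construction: a fixed reference tag
count would make sqrt(c) constant across samples and carry no
presence/absence information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_WIDTH = 1_000_000


@dataclass(frozen=True)
class BinGrid:
    """Non-overlapping 1 Mb windows tiling one region (the last window may
    be shorter)."""

    region: str
    length: int
    width: int = BIN_WIDTH

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("region length and bin width must be positive")

    @property
    def n_bins(self) -> int:
        return -(-self.length // self.width)

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.width

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.width, self.length)

    @property
    def labels(self) -> list[str]:
        return [f"{self.region}:{s}-{e}" for s, e in zip(self.starts, self.ends)]


@dataclass
class TagIndexMatrix:
    """Tag index per bin per sample, with the c and d components retained."""

    index: pd.DataFrame  # bins x samples, sqrt(c) + d
    c: pd.DataFrame  # observed tag-site counts
    d: pd.DataFrame  # summed RPM depth
    bins: pd.DataFrame = field(default=None)  # bin_id -> region, start, end

    def __post_init__(self) -> None:
        if not (self.index.index.equals(self.c.index) and self.index.index.equals(self.d.index)):
            raise ValueError("component matrices not aligned")


def bin_tags(tags: pd.DataFrame, grid: BinGrid) -> pd.Series:
    """Assign each tag on the grid's region to a bin by its start coordinate.

    Tags on other regions, or starting beyond the region length, are left
    unassigned (absent from the result).
    """
    on = tags[(tags["chrom"] == grid.region) & (tags["start"] < grid.length) & (tags["start"] >= 0)]
    return (on["start"] // grid.width).astype(int)


def tag_index(
    depth: pd.DataFrame, assignment: pd.Series, grid: BinGrid
) -> TagIndexMatrix:
    """Compute sqrt(c) + d per bin per sample from an RPM depth matrix.

    ``assignment`` maps tag_id -> bin number on ``grid`` (from
    :func:`bin_tags`). Bins with no tags, or no observed tags in a sample,
    score 0.
    """
    labels = grid.labels
    tag_ids = assignment.index.intersection(depth.index)
    assignment = assignment.loc[tag_ids]
    sub = depth.loc[tag_ids]
    bins = assignment.to_numpy()
    vals = sub.to_numpy(dtype=float)

    n_bins = grid.n_bins
    d = np.zeros((n_bins, vals.shape[1]))
    c = np.zeros((n_bins, vals.shape[1]))
    np.add.at(d, bins, vals)
    np.add.at(c, bins, (vals > 0).astype(float))

    cols = sub.columns
    c_df = pd.DataFrame(c, index=labels, columns=cols)
    d_df = pd.DataFrame(d, index=labels, columns=cols)
    idx = np.sqrt(c) + d
    bins_df = pd.DataFrame(
        {"region": grid.region, "start": grid.starts, "end": grid.ends}, index=labels
    )
    return TagIndexMatrix(pd.DataFrame(idx, index=labels, columns=cols), c_df, d_df, bins_df)


def tag_index_regions(
    depth: pd.DataFrame, tags: pd.DataFrame, grids: list[BinGrid]
) -> TagIndexMatrix:
    """Tag index over several regions, bins concatenated in grid order."""
    parts = [tag_index(depth, bin_tags(tags, g), g) for g in grids]
    return TagIndexMatrix(
        pd.concat([p.index for p in parts]),
        pd.concat([p.c for p in parts]),
        pd.concat([p.d for p in parts]),
        pd.concat([p.bins for p in parts]),
    )


def minmax_scale(mat: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Min/max scale each bin (row) to [0, 1] over the given sample set.

    Scaling is a per-feature transform recomputed within every clustering
    batch over exactly the batch's samples, so each k-means run sees
    features on [0, 1] regardless of membership. Constant bins scale to 0.
    """
    sub = mat if samples is None else mat[list(samples)]
    x = sub.to_numpy(dtype=float)
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0
    out = (x - lo) / span
    out[(hi - lo).ravel() == 0, :] = 0.0
    return pd.DataFrame(out, index=sub.index, columns=sub.columns)


def to_long_table(tim: TagIndexMatrix, scaled: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format export: bin_id, region, start, end, sample, c, d, index
    (plus scaled_index when provided)."""
    rows = []
    for comp, name in ((tim.c, "c"), (tim.d, "d"), (tim.index, "index")):
        rows.append(comp.stack().rename(name))
    if scaled is not None:
        rows.append(scaled.stack().rename("scaled_index"))
    long = pd.concat(rows, axis=1).reset_index()
    long.columns = ["bin_id", "sample"] + list(long.columns[2:])
    long = long.merge(tim.bins, left_on="bin_id", right_index=True)
    cols = ["bin_id", "region", "start", "end", "sample", "c", "d", "index"]
    if scaled is not None:
        cols.append("scaled_index")
    return long[cols]
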