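"""Synthetic GBS tag-count cohorts with known drive-haplotype truth.

The generator emulates the count-level structure the detector relies on:

* tag sites scattered over normal chromosomes (diploid dosage everywhere);
* haplotype regions whose leading bins are homologous to the normal genome
  (signal in every sample) and whose remaining bins are haplotype-specific
  (signal only in carriers, proportional to copy number);
* cross-mapping homology from Ab10 onto the K10L2-specific region — both
  haplotypes carry the TR-1/trkin region, which is why the K10L2 features
  cannot distinguish the two and the stepwise call order exists;
* Ab10 cytological types as per-bin dosage profiles over the haplotype;
* B-chromosome copy numbers from 0 up to 14;
* single-copy core genes on a normal chromosome (the copy-number baseline);
* log-normal library-size variation, Poisson read counts, no-DNA blank
  lanes, and a mapping-quality mix with a low-MAPQ tail.

Counts are Poisson: count[t, s] ~ Pois(lib_s * depth * w_t * rate(t, s))
where w_t is a per-tag efficiency (Gamma, mean 1) and rate is the local
dosage of the tag in that sample plus a small cross-mapping background.
The ``signal`` parameter scales haplotype-specific dosage relative to that
background and is the effect-size dial: 1.0 reproduces the stark
positive/negative contrast of real control panels, values near the
background rate approach overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import META_COLUMNS, TagByTaxa

AB10_TYPES = ("Ab10-I", "Ab10-II", "Ab10-III")


@dataclass(frozen=True)
class CDHRegion:
    """One haplotype region of the synthetic reference."""

    name: str
    cdh: str  # "Ab10" | "K10L2" | "B"
    n_bins: int
    shared_bins: int  # leading bins homologous to the normal genome


@dataclass
class SimLayout:
    """Synthetic reference description: regions, tag density, homology.

    ``ab10_type_profiles`` gives, per cytological type, a dosage multiplier
    for every bin of the Ab10 region (1 = carried, 0 = absent); shared bins
    are ignored there. ``cross_homology`` is the dosage an Ab10 copy
    contributes to K10L2-specific tags. ``specific_weight`` down-weights
    reads from haplotype-specific tags relative to normal-genome tags: the
    drive haplotypes are repetitive and poorly conserved, so fewer reads
    align per Mb than in gene space — the reason relative tag indices are
    not integer copy numbers.
    """

    normal_chroms: dict[str, int] = field(
        default_factory=lambda: {"chr1": 40, "chr2": 20}
    )  # name -> length in Mb
    cdh_regions: tuple[CDHRegion, ...] = (
        CDHRegion("ab10_hap", "Ab10", 24, 4),
        CDHRegion("k10l2_hap", "K10L2", 12, 2),
        CDHRegion("chrB", "B", 16, 1),
    )
    core_genes: pd.DataFrame | None = None  # chrom, start, end; default built below
    tags_per_mb: int = 40
    mapq_low_fraction: float = 0.10
    cross_homology: float = 1.0
    specific_weight: float = 0.4
    ab10_type_profiles: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.core_genes is None:
            # 60 single-copy core-gene blocks of 150 kb on chr1 -> 9 Mb of
            # gene space (a quiet, well-sampled single-copy baseline)
            starts = 200_000 + 600_000 * np.arange(60)
            self.core_genes = pd.DataFrame(
                {"chrom": "chr1", "start": starts, "end": starts + 150_000}
            )
        if not self.ab10_type_profiles:
            ab10 = self.region("Ab10")
            self.ab10_type_profiles = default_type_profiles(ab10.n_bins, ab10.shared_bins)

    def region(self, cdh: str) -> CDHRegion:
        for r in self.cdh_regions:
            if r.cdh == cdh:
                return r
        raise KeyError(cdh)

    @property
    def region_lengths(self) -> dict[str, int]:
        out = {c: mb * 1_000_000 for c, mb in self.normal_chroms.items()}
        out.update({r.name: r.n_bins * 1_000_000 for r in self.cdh_regions})
        return out


def default_type_profiles(n_bins: int, shared_bins: int) -> dict[str, np.ndarray]:
    """Bin dosage profiles for the three Ab10 types.

    A block of bins common to all types carries the presence signal; three
    trailing blocks are carried by exactly one type each, mimicking the
    knob/gene content differences between cytological types.
    """
    specific = n_bins - shared_bins
    if specific < 10:
        raise ValueError("Ab10 region too small for type profiles")
    n_type = max(2, specific // 5)
    profiles = {}
    for i, t in enumerate(AB10_TYPES):
        p = np.ones(n_bins)
        p[:shared_bins] = 0.0  # shared bins get diploid dosage separately
        own = slice(n_bins - (3 - i) * n_type, n_bins - (2 - i) * n_type)
        for j, other in enumerate(AB10_TYPES):
            blk = slice(n_bins - (3 - j) * n_type, n_bins - (2 - j) * n_type)
            p[blk] = 1.0 if other == t else 0.0
        del own
        profiles[t] = p
    return profiles


@dataclass
class SimCohortSpec:
    """Generation parameters of a synthetic cohort.

    Frequencies refer to the experimental survey regime (landrace-like:
    a few percent Ab10 and K10L2, ~12% carrying at least one B).
    """

    n_samples: int = 100
    freq_ab10: float = 0.06
    freq_k10l2: float = 0.05
    freq_b: float = 0.12
    ab10_type_probs: dict[str, float] = field(
        default_factory=lambda: {t: 1 / 3 for t in AB10_TYPES}
    )
    ab10_hom_fraction: float = 0.10
    k10l2_hom_fraction: float = 0.10
    b_copy_range: tuple[int, int] = (1, 8)
    depth_per_copy: float = 4.0  # mean reads per tag per haplotype copy
    lib_sigma: float = 0.4  # log-normal sd of library-size factors
    background_rate: float = 0.02  # cross-mapping dosage onto specific tags
    signal: float = 1.0  # effect-size dial on haplotype-specific dosage
    blank_rate: float = 0.002  # residual dosage in no-DNA lanes
    n_blanks: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.freq_ab10 + self.freq_k10l2 > 1:
            raise ValueError("chromosome-10 haplotype frequencies exceed 1")
        if abs(sum(self.ab10_type_probs.values()) - 1) > 1e-9:
            raise ValueError("ab10_type_probs must sum to 1")
        if not (0 < self.signal <= 1):
            raise ValueError("signal must be in (0, 1]")


def preset(name: str) -> SimCohortSpec:
    """Named generation regimes: 'strong' (stark control contrast) and
    'hard' (specific signal close to the cross-mapping background)."""
    if name == "strong":
        return SimCohortSpec()
    if name == "hard":
        return SimCohortSpec(signal=0.05)
    raise KeyError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# Tag universe
# ---------------------------------------------------------------------------

@dataclass
class TagUniverse:
    """Realized tag sites of a layout: coordinates, MAPQ, efficiency and the
    dosage role of every tag."""

    tags: pd.DataFrame  # tag_id-indexed: chrom, start, end, mapq
    weight: np.ndarray  # per-tag efficiency, mean 1
    role: np.ndarray  # 'normal' | 'shared' | cdh name ('Ab10'/'K10L2'/'B')
    bin_in_region: np.ndarray  # bin number within its region (-1 for normal)
    layout: SimLayout


def realize_tags(layout: SimLayout, rng: np.random.Generator) -> TagUniverse:
    chroms, starts, roles, bins = [], [], [], []

    def _add(chrom: str, length: int, role_per_bin) -> None:
        n = int(layout.tags_per_mb * length / 1_000_000)
        pos = np.sort(rng.integers(0, length - 64, size=n))
        chroms.extend([chrom] * n)
        starts.extend(pos.tolist())
        b = pos // 1_000_000
        bins.extend(b.tolist())
        roles.extend([role_per_bin(int(x)) for x in b])

    for chrom, mb in layout.normal_chroms.items():
        _add(chrom, mb * 1_000_000, lambda b: "normal")
    for r in layout.cdh_regions:
        _add(
            r.name,
            r.n_bins * 1_000_000,
            lambda b, r=r: "shared" if b < r.shared_bins else r.cdh,
        )

    n = len(starts)
    ids = [f"T{i:06d}" for i in range(n)]
    mapq = np.where(
        rng.random(n) < layout.mapq_low_fraction, rng.integers(0, 20, size=n), 60
    )
    tags = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.array(starts),
            "end": np.array(starts) + 64,
            "mapq": mapq,
        },
        index=pd.Index(ids, name="tag_id"),
    )
    weight = rng.gamma(4.0, 0.25, size=n)
    bin_arr = np.array(bins)
    role_arr = np.array(roles, dtype=object)
    bin_arr = np.where(role_arr == "normal", -1, bin_arr)
    return TagUniverse(tags, weight, role_arr, bin_arr, layout)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["sample_id", "cdh", "ab10_type", "ab10_copies", "k10l2_copies", "b_copies"]


def simulate_counts(
    universe: TagUniverse,
    truth: pd.DataFrame,
    spec: SimCohortSpec,
    rng: np.random.Generator,
) -> TagByTaxa:
    """Poisson tag counts for the samples described in ``truth``.

    ``truth`` rows need sample_id, ab10_type (or NA), ab10_copies,
    k10l2_copies, b_copies and a boolean ``blank`` column.
    """
    layout = universe.layout
    n_tags = len(universe.tags)
    n_samples = len(truth)
    dosage = np.zeros((n_tags, n_samples))

    is_normal = universe.role == "normal"
    is_shared = universe.role == "shared"
    spec_mask = {cdh: universe.role == cdh for cdh in ("Ab10", "K10L2", "B")}
    ab10_bins = universe.bin_in_region[spec_mask["Ab10"]]

    for j, row in enumerate(truth.itertuples(index=False)):
        if row.blank:
            dosage[:, j] = 0.0
            continue
        dosage[is_normal | is_shared, j] = 2.0
        ab10_c = float(row.ab10_copies)
        if ab10_c > 0:
            profile = layout.ab10_type_profiles[row.ab10_type]
            dosage[spec_mask["Ab10"], j] = ab10_c * profile[ab10_bins] * spec.signal
        k_dose = float(row.k10l2_copies) + layout.cross_homology * ab10_c
        if k_dose > 0:
            dosage[spec_mask["K10L2"], j] = k_dose * spec.signal
        if row.b_copies > 0:
            dosage[spec_mask["B"], j] = float(row.b_copies) * spec.signal

    # cross-mapping background onto every haplotype-specific tag
    any_specific = spec_mask["Ab10"] | spec_mask["K10L2"] | spec_mask["B"]
    bg = np.where(any_specific, 2.0 * spec.background_rate, 0.0)

    lib = rng.lognormal(mean=0.0, sigma=spec.lib_sigma, size=n_samples)
    rate = dosage + bg[:, None]
    blank_col = truth["blank"].to_numpy(dtype=bool)
    rate[:, blank_col] = spec.blank_rate
    # haplotype-specific tags yield fewer aligned reads (repetitive, poorly
    # conserved sequence) than normal-genome tags
    w_eff = universe.weight * np.where(any_specific, layout.specific_weight, 1.0)
    lam = spec.depth_per_copy * w_eff[:, None] * lib[None, :] * rate
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(
        counts, index=universe.tags.index, columns=list(truth["sample_id"])
    )
    return TagByTaxa(universe.tags.copy(), counts_df)


def _blank_truth(ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ids,
            "cdh": "none",
            "ab10_type": pd.NA,
            "ab10_copies": 0,
            "k10l2_copies": 0,
            "b_copies": 0,
            "blank": True,
        }
    )


def simulate_cohort(
    layout: SimLayout,
    spec: SimCohortSpec,
    rng: np.random.Generator | None = None,
    universe: TagUniverse | None = None,
    prefix: str = "EXP",
) -> tuple[TagByTaxa, pd.DataFrame, pd.DataFrame]:
    """An experimental cohort drawn from the spec's frequencies.

    Returns (TagByTaxa, sample metadata, truth table). Pass an existing
    ``universe`` to share tag sites with another cohort (e.g. a control
    panel simulated on the same reference).
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    if universe is None:
        universe = realize_tags(layout, rng)

    n = spec.n_samples
    u = rng.random(n)
    cdh = np.full(n, "none", dtype=object)
    cdh[u < spec.freq_ab10] = "Ab10"
    cdh[(u >= spec.freq_ab10) & (u < spec.freq_ab10 + spec.freq_k10l2)] = "K10L2"
    types = list(spec.ab10_type_probs)
    probs = np.array([spec.ab10_type_probs[t] for t in types])

    rows = []
    for i in range(n):
        sid = f"{prefix}_{i:04d}"
        ab10_type = pd.NA
        ab10_copies = k10l2_copies = 0
        if cdh[i] == "Ab10":
            ab10_type = types[int(rng.choice(len(types), p=probs))]
            ab10_copies = 2 if rng.random() < spec.ab10_hom_fraction else 1
        elif cdh[i] == "K10L2":
            k10l2_copies = 2 if rng.random() < spec.k10l2_hom_fraction else 1
        b_copies = 0
        if rng.random() < spec.freq_b:
            b_copies = int(rng.integers(spec.b_copy_range[0], spec.b_copy_range[1] + 1))
        label = cdh[i] if cdh[i] != "Ab10" else ab10_type
        rows.append(
            dict(sample_id=sid, cdh=label, ab10_type=ab10_type, ab10_copies=ab10_copies,
                 k10l2_copies=k10l2_copies, b_copies=b_copies, blank=False)
        )
    truth = pd.DataFrame(rows)
    if spec.n_blanks:
        truth = pd.concat(
            [truth, _blank_truth([f"BLANK_{prefix}_{i:02d}" for i in range(spec.n_blanks)])],
            ignore_index=True,
        )

    tbt = simulate_counts(universe, truth, spec, rng)
    meta = pd.DataFrame(
        {
            "sample_id": truth["sample_id"],
            "role": np.where(truth["blank"], "blank", "experimental"),
            "control_cdh": pd.NA,
            "copy_stratum": pd.NA,
            "ab10_type": pd.NA,
            "replicate_group": pd.NA,
        }
    )[META_COLUMNS]
    return tbt, meta, truth


def make_control_panel(
    layout: SimLayout,
    spec: SimCohortSpec | None = None,
    rng: np.random.Generator | None = None,
    universe: TagUniverse | None = None,
    n_ab10: int = 49,
    n_k10l2: int = 13,
    n_b: int = 18,
    n_negative: int = 18,
    n_blanks: int = 3,
    ab10_hom: int = 12,
    k10l2_hom: int = 5,
    b_high: int = 13,
) -> tuple[TagByTaxa, pd.DataFrame, pd.DataFrame]:
    """A control panel mirroring the published panel sizes.

    Defaults: 49 Ab10 controls across the three types (12 of them
    homozygous), 13 K10L2 (5 homozygous), 18 B-positive split into high- and
    low-copy strata, 18 negative controls and 3 blank lanes. Ab10/K10L2
    homozygotes are the high-copy stratum; B high-copy controls carry 4-8
    copies and low-copy controls 1-2. The low-copy B stratum is deliberately
    small — too few samples to subsample into validation groups, so it is
    clustered as a single group, matching the published design.
    """
    if spec is None:
        spec = preset("strong")
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    if universe is None:
        universe = realize_tags(layout, rng)

    rows = []

    type_counts = _split_counts(n_ab10, len(AB10_TYPES))
    hom_left = ab10_hom
    k = 0
    for t, ct in zip(AB10_TYPES, type_counts):
        homs = min(ct // 3, hom_left)
        hom_left -= homs
        suffix = t.split("-")[1]
        for i in range(ct):
            copies = 2 if i < homs else 1
            rows.append(
                dict(sample_id=f"CTRL_AB10{suffix}_{k:03d}",
                     cdh=t, ab10_type=t, ab10_copies=copies, k10l2_copies=0,
                     b_copies=0, blank=False)
            )
            k += 1

    for i in range(n_k10l2):
        copies = 2 if i < k10l2_hom else 1
        rows.append(
            dict(sample_id=f"CTRL_K10L2_{i:03d}", cdh="K10L2", ab10_type=pd.NA,
                 ab10_copies=0, k10l2_copies=copies, b_copies=0, blank=False)
        )

    high_copies = [4, 6, 8]
    low_copies = [1, 2]
    for i in range(n_b):
        if i < b_high:
            c = high_copies[i % len(high_copies)]
        else:
            c = low_copies[i % len(low_copies)]
        rows.append(
            dict(sample_id=f"CTRL_B_{i:03d}", cdh="B", ab10_type=pd.NA,
                 ab10_copies=0, k10l2_copies=0, b_copies=c, blank=False)
        )

    for i in range(n_negative):
        rows.append(
            dict(sample_id=f"CTRL_NEG_{i:03d}", cdh="none", ab10_type=pd.NA,
                 ab10_copies=0, k10l2_copies=0, b_copies=0, blank=False)
        )

    truth = pd.DataFrame(rows)
    if n_blanks:
        truth = pd.concat(
            [truth, _blank_truth([f"BLANK_{i:02d}" for i in range(n_blanks)])],
            ignore_index=True,
        )
    tbt = simulate_counts(universe, truth, spec, rng)

    def _stratum(r) -> object:
        if r.cdh in AB10_TYPES:
            return "high" if r.ab10_copies == 2 else "low"
        if r.cdh == "K10L2":
            return "high" if r.k10l2_copies == 2 else "low"
        if r.cdh == "B":
            return "high" if r.b_copies >= 3 else "low"
        return pd.NA

    meta = pd.DataFrame(
        {
            "sample_id": truth["sample_id"],
            "role": np.where(truth["blank"], "blank", "control"),
            "control_cdh": [
                pd.NA if r.blank else ("Ab10" if r.cdh in AB10_TYPES else r.cdh)
                for r in truth.itertuples()
            ],
            "copy_stratum": [pd.NA if r.blank else _stratum(r) for r in truth.itertuples()],
            "ab10_type": truth["ab10_type"],
            "replicate_group": pd.NA,
        }
    )[META_COLUMNS]
    return tbt, meta, truth


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    rem = total - base * parts
    return [base + (1 if i < rem else 0) for i in range(parts)]


def simulate_study(
    layout: SimLayout,
    cohort_spec: SimCohortSpec,
    seed: int,
    panel_kwargs: dict | None = None,
) -> tuple[TagByTaxa, pd.DataFrame, pd.DataFrame]:
    """Control panel + experimental cohort on one shared tag universe.

    Returns combined (TagByTaxa, metadata, truth).
    """
    rng = np.random.default_rng(seed)
    universe = realize_tags(layout, rng)
    panel_tbt, panel_meta, panel_truth = make_control_panel(
        layout, cohort_spec, rng, universe, **(panel_kwargs or {})
    )
    cohort_tbt, cohort_meta, cohort_truth = simulate_cohort(
        layout, cohort_spec, rng, universe
    )
    tbt = TagByTaxa(
        universe.tags.copy(), pd.concat([panel_tbt.counts, cohort_tbt.counts], axis=1)
    )
    meta = pd.concat([panel_meta, cohort_meta], ignore_index=True)
    truth = pd.concat([panel_truth, cohort_truth], ignore_index=True)
    return tbt, meta, truth


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(
    tbt: TagByTaxa, meta: pd.DataFrame, truth: pd.DataFrame, out_dir
) -> dict[str, Path]:
    """Write counts TSV + tag BED + metadata TSV + truth TSV; re-reading
    reproduces the matrices exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "tags": out / "tags.bed",
        "meta": out / "meta.tsv",
        "truth": out / "truth.tsv",
    }
    tbt.counts.to_csv(paths["counts"], sep="\t", index_label="tag_id")
    bed = tbt.tags.reset_index()[["chrom", "start", "end", "tag_id", "mapq"]]
    bed.to_csv(paths["tags"], sep="\t", index=False, header=False)
    meta.to_csv(paths["meta"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
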