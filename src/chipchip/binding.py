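"""Strain-contrast binding-region calling on tiling-array ChIP data.

The caller compares the complemented strain (carrying the tagged regulator)
against the deletion strain. A probe is a *candidate* when its oriented,
normalized enrichment ratio is strictly larger in the complemented strain
in every paired replicate; candidates whose fold change (mean complemented
minus mean deleted) exceeds the candidate mean by more than one sample
standard deviation are *enriched*. Enriched probes within a maximum genomic
gap of each other cluster into binding regions; regions are annotated
against gene models and their enrichment profile is classified as
monophasic (single summit) or biphasic (asymmetric double summit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import GenomeAnnotation

SHAPE_MONOPHASIC = "monophasic"
SHAPE_BIPHASIC = "biphasic"
SHAPE_UNCLASSIFIED = "unclassified"

LOC_PROMOTER = "promoter_proximal"
LOC_INTERNAL = "gene_internal"
LOC_INTERGENIC = "intergenic"


@dataclass
class ClusterParams:
    """Clustering rule: enriched probes within ``max_gap`` bp join one
    region; clusters with fewer than ``min_probes`` members are dropped.

    ``method`` selects between single-linkage gap clustering ("gap",
    default: consecutive probes join when their midpoint gap is <= max_gap)
    and the alternative fixed-span reading ("span": additionally splits any
    cluster whose midpoint span exceeds max_gap).
    """

    max_gap: int = 1000
    min_probes: int = 2
    method: str = "gap"

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValueError("max_gap must be > 0")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.method not in ("gap", "span"):
            raise ValueError(f"unknown clustering method {self.method!r}")


@dataclass
class ShapeParams:
    """Peak-shape classification knobs (validated against synthetic truth)."""

    smooth_window: int = 3
    min_prominence_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if not (0 < self.min_prominence_frac < 1):
            raise ValueError("min_prominence_frac must be in (0, 1)")


@dataclass
class EnrichedProbeSet:
    """Per-probe contrast fold changes with candidate/enriched status.

    ``threshold = fc_mean + 1.0 * fc_sd`` where the mean and (sample,
    n-1 denominator) standard deviation are taken over candidate probes
    only. ``is_enriched`` iff candidate and fold_change strictly above the
    threshold.
    """

    probe_ids: np.ndarray
    fold_change: np.ndarray
    is_candidate: np.ndarray
    is_enriched: np.ndarray
    fc_mean: float
    fc_sd: float
    threshold: float

    @property
    def n_candidates(self) -> int:
        return int(self.is_candidate.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "fold_change": self.fold_change,
                "is_candidate": self.is_candidate,
                "is_enriched": self.is_enriched,
            }
        )


def call_enriched_probes(
    complemented: np.ndarray, deleted: np.ndarray, probe_ids: np.ndarray | None = None
) -> EnrichedProbeSet:
    """Call enriched probes from paired replicate values of the two strains.

    ``complemented`` and ``deleted`` are (n_probes, n_replicates) matrices of
    oriented, normalized log2 enrichment ratios, with replicates paired by
    column index. QC-excluded probes must already be absent; probes with a
    missing value in any replicate are ineligible as candidates but still
    get a fold change where computable.
    """
    x = np.asarray(complemented, dtype=float)
    d = np.asarray(deleted, dtype=float)
    if x.ndim != 2 or d.shape != x.shape:
        raise ValueError("complemented and deleted must be equal-shape (probes x reps) matrices")
    if x.shape[1] < 2:
        raise ValueError("candidate rule needs at least two paired replicates")
    n = x.shape[0]
    if probe_ids is None:
        probe_ids = np.arange(n).astype(str)
    probe_ids = np.asarray(probe_ids)

    complete = np.isfinite(x).all(axis=1) & np.isfinite(d).all(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fold_change = np.nanmean(x, axis=1) - np.nanmean(d, axis=1)
    is_candidate = complete & (x > d).all(axis=1)

    n_cand = int(is_candidate.sum())
    if n_cand < 2:
        warnings.warn(
            f"only {n_cand} candidate probe(s); standard deviation undefined, "
            "no enrichment calls made",
            stacklevel=2,
        )
        return EnrichedProbeSet(
            probe_ids=probe_ids,
            fold_change=fold_change,
            is_candidate=is_candidate,
            is_enriched=np.zeros(n, dtype=bool),
            fc_mean=float("nan"),
            fc_sd=float("nan"),
            threshold=float("nan"),
        )

    cand_fc = fold_change[is_candidate]
    fc_mean = float(np.mean(cand_fc))
    fc_sd = float(np.std(cand_fc, ddof=1))
    threshold = fc_mean + 1.0 * fc_sd
    is_enriched = is_candidate & (fold_change > threshold)
    return EnrichedProbeSet(
        probe_ids=probe_ids,
        fold_change=fold_change,
        is_candidate=is_candidate,
        is_enriched=is_enriched,
        fc_mean=fc_mean,
        fc_sd=fc_sd,
        threshold=threshold,
    )


@dataclass
class BindingRegion:
    """A clustered genomic segment of enriched probes (1-based inclusive)."""

    region_id: str
    chrom: str
    start: int
    end: int
    probe_ids: list = field(default_factory=list)
    n_probes: int = 0
    max_fold_change: float = float("nan")
    shape: str = SHAPE_UNCLASSIFIED
    summits: list = field(default_factory=list)
    overlapping_genes: list = field(default_factory=list)
    location_class: str | None = None


def probe_midpoint(start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Genomic position of a probe = midpoint of its [start, end] span."""
    return (np.asarray(start) + np.asarray(end)) / 2.0


def cluster_regions(enriched: pd.DataFrame, params: ClusterParams, chrom: str | None = None) -> list[BindingRegion]:
    """Single-linkage cluster enriched probes into binding regions.

    ``enriched`` needs columns probe_id, start, end, fold_change (one row
    per enriched probe). Consecutive probes (by midpoint) join one cluster
    iff their gap is <= ``max_gap`` (boundary inclusive); clusters with at
    least ``min_probes`` members become regions spanning min(start) to
    max(end) of their member probes.
    """
    if len(enriched) == 0:
        return []
    if chrom is None:
        chrom = str(enriched["chrom"].iloc[0]) if "chrom" in enriched.columns else "chr"
    df = enriched.copy()
    df["midpoint"] = probe_midpoint(df["start"].to_numpy(), df["end"].to_numpy())
    df = df.sort_values("midpoint", kind="stable").reset_index(drop=True)

    mids = df["midpoint"].to_numpy()
    gaps = np.diff(mids)
    # new cluster starts where the gap to the previous probe exceeds max_gap
    cluster_id = np.concatenate([[0], np.cumsum(gaps > params.max_gap)])

    if params.method == "span":
        cluster_id = _split_by_span(mids, cluster_id, params.max_gap)

    regions: list[BindingRegion] = []
    for cid in np.unique(cluster_id):
        members = df.loc[cluster_id == cid]
        if len(members) < params.min_probes:
            continue
        regions.append(
            BindingRegion(
                region_id="",
                chrom=chrom,
                start=int(members["start"].min()),
                end=int(members["end"].max()),
                probe_ids=members["probe_id"].tolist(),
                n_probes=len(members),
                max_fold_change=float(members["fold_change"].max()),
            )
        )
    regions.sort(key=lambda r: r.start)
    for i, r in enumerate(regions, 1):
        r.region_id = f"region_{i:03d}"
    return regions


def _split_by_span(mids: np.ndarray, cluster_id: np.ndarray, max_span: float) -> np.ndarray:
    """Greedy left-to-right split so each cluster's midpoint span <= max_span."""
    out = cluster_id.copy()
    next_id = out.max() + 1
    for cid in np.unique(cluster_id):
        idx = np.flatnonzero(cluster_id == cid)
        anchor = mids[idx[0]]
        cur = out[idx[0]]
        for i in idx[1:]:
            if mids[i] - anchor > max_span:
                cur = next_id
                next_id += 1
                anchor = mids[i]
            out[i] = cur
    return out


def annotate_regions(
    regions: list[BindingRegion],
    annotation: GenomeAnnotation,
    promoter_window: int = 300,
) -> list[BindingRegion]:
    """Attach overlapping genes and a location class to each region.

    location_class: ``gene_internal`` when at least half the region's length
    lies inside a single gene; else ``promoter_proximal`` when the region
    intersects the coding-strand upstream window of some gene; else
    ``intergenic``.
    """
    genes = annotation.genes
    known_chroms = set(genes["chrom"]) if len(genes) else set()
    for region in regions:
        if len(genes) and region.chrom not in known_chroms:
            raise ValueError(f"region {region.region_id}: unknown chromosome {region.chrom!r}")
        r_len = region.end - region.start + 1
        overlapping = []
        internal = False
        promoter = False
        for g in genes.itertuples(index=False):
            if g.chrom != region.chrom:
                continue
            ov = min(region.end, g.end) - max(region.start, g.start) + 1
            if ov > 0:
                overlapping.append(g.gene_id)
                if ov >= 0.5 * r_len:
                    internal = True
            # coding-strand upstream window: [start - w, start] for +,
            # [end, end + w] for -
            if g.strand == "+":
                up_lo, up_hi = g.start - promoter_window, g.start
            else:
                up_lo, up_hi = g.end, g.end + promoter_window
            up_lo = max(up_lo, 1)
            if min(region.end, up_hi) - max(region.start, up_lo) + 1 > 0:
                promoter = True
        region.overlapping_genes = overlapping
        if internal:
            region.location_class = LOC_INTERNAL
        elif promoter:
            region.location_class = LOC_PROMOTER
        else:
            region.location_class = LOC_INTERGENIC
    return regions


def _smooth_profile(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average ignoring missing values (mask-weighted)."""
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(v)
    filled = np.where(mask, v, 0.0)
    kernel = np.ones(window)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(mask.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def classify_peak_shape(
    region: BindingRegion,
    positions: np.ndarray,
    profile: np.ndarray,
    threshold: float,
    params: ShapeParams | None = None,
    probe_spacing: float | None = None,
) -> BindingRegion:
    """Classify a region's enrichment profile as monophasic or biphasic.

    ``positions``/``profile`` give the per-probe fold-change profile over the
    region extended by the clustering gap on both flanks. The profile is
    smoothed with a centered moving average and local maxima are found. The
    major (tallest) summit must clear the probe-level enrichment threshold;
    a second summit only needs to reach half the threshold, since a genuine
    minor peak of an asymmetric pair can sit below the probe-calling cutoff
    while still being visually unambiguous. The region is biphasic iff such
    a second maximum exists whose separating trough drops below
    ``(1 - min_prominence_frac) x (smaller maximum)`` and whose separation
    from the major summit is at least two probe spacings. Summits are the
    positions of the 1 or 2 retained maxima, major summit first.
    """
    params = params or ShapeParams()
    positions = np.asarray(positions, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if len(positions) != len(profile):
        raise ValueError("positions and profile must have equal length")
    finite = np.isfinite(profile)
    if not finite.any():
        region.shape = SHAPE_UNCLASSIFIED
        region.summits = []
        return region
    if probe_spacing is None:
        diffs = np.diff(positions)
        probe_spacing = float(np.median(diffs)) if len(diffs) else 1.0

    smoothed = _smooth_profile(profile, params.smooth_window)
    work = np.where(np.isfinite(smoothed), smoothed, -np.inf)
    peak_idx, _ = find_peaks(work)
    has_threshold = np.isfinite(threshold)
    if has_threshold:
        # the major summit must itself clear the enrichment threshold
        major_pool = peak_idx[work[peak_idx] > threshold]
        minor_floor = 0.5 * threshold
    else:
        major_pool = peak_idx
        minor_floor = -np.inf

    if len(major_pool) == 0:
        # flat-topped or edge profile: fall back to the global maximum
        apex = int(np.nanargmax(np.where(np.isfinite(smoothed), smoothed, -np.inf)))
        region.shape = SHAPE_MONOPHASIC
        region.summits = [float(positions[apex])]
        return region

    major = int(major_pool[np.argmax(work[major_pool])])
    minors = peak_idx[(peak_idx != major) & (work[peak_idx] >= minor_floor)]
    order = minors[np.argsort(work[minors])[::-1]]
    for cand in order:
        cand = int(cand)
        lo, hi = sorted((major, cand))
        trough = np.nanmin(np.where(np.isfinite(smoothed[lo:hi + 1]), smoothed[lo:hi + 1], np.inf))
        smaller = min(work[major], work[cand])
        separated = abs(positions[cand] - positions[major]) >= 2 * probe_spacing
        if separated and trough < (1 - params.min_prominence_frac) * smaller:
            region.shape = SHAPE_BIPHASIC
            region.summits = [float(positions[major]), float(positions[cand])]
            return region
    region.shape = SHAPE_MONOPHASIC
    region.summits = [float(positions[major])]
    return region
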