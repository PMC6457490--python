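"""Per-gene expression summarization and Rank Product differential expression.

The Rank Product statistic for an unpaired two-class design with nA and nB
replicates forms K = nA x nB pairwise log fold differences, ranks genes
within each comparison (rank 1 = most extreme in the tested direction,
ties = average ranks) and takes the geometric mean of a gene's K ranks:

    RP_g = (prod_k r_gk)^(1/K)

A consistently extreme gene has RP near 1. Significance is estimated by
Monte-Carlo simulation of the null: B pseudo-datasets of i.i.d. replicate
values are drawn, the same K crossed differences are formed and ranked, and
the resulting null RP values are pooled. Because the K comparisons share
replicates, their ranks are correlated; simulating the crossing (rather
than permuting each comparison's ranks independently) reproduces that
correlation, and since ranks of crossed differences of i.i.d. continuous
variables are distribution-free, the simulated null is exact under the
hypothesis of exchangeable noise. A second, conditional pass offsets null
ranks by the number of confidently non-null genes, which in data displace
true nulls down every ranking. The expected number of null RP values at or
below a gene's RP, divided by the gene's position in the RP ordering, is
the percentage-of-false-positives (pfp) for selecting all genes up to that
position. pfp values are smoothed by a cumulative minimum from the largest
RP downward so the cutoff is well-defined.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import rankdata

from .io import GenomeAnnotation
from .preprocess import FilterReport

DIR_UP = "up_in_complemented"
DIR_DOWN = "down_in_complemented"


def gene_signals(
    values: np.ndarray,
    probes: pd.DataFrame,
    annotation: GenomeAnnotation,
    filter_report: FilterReport | None = None,
) -> pd.DataFrame:
    """Average good-quality probes over each gene's coding region.

    ``values`` is a (n_probes, n_samples) oriented, normalized expression
    matrix aligned with ``probes`` rows. A probe targets a gene iff its
    interval intersects the gene's span (1-based inclusive); a probe
    spanning two overlapping genes contributes to both. Genes with zero
    good probes get NaN. Returns a genes x samples frame with an extra
    ``n_probes`` column.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    excluded = filter_report.excluded_probe_ids if filter_report is not None else set()
    keep = ~probes["probe_id"].isin(excluded).to_numpy()
    values = np.asarray(values, dtype=float)

    # interval tree over good probes; +1 on end for half-open tree intervals
    tree = IntervalTree()
    for i in np.flatnonzero(keep):
        tree.addi(int(probes["start"].iloc[i]), int(probes["end"].iloc[i]) + 1, i)

    n_samples = values.shape[1]
    rows = []
    counts = []
    gene_ids = []
    for g in annotation.genes.itertuples(index=False):
        hits = sorted(iv.data for iv in tree.overlap(g.start, g.end + 1))
        gene_ids.append(g.gene_id)
        counts.append(len(hits))
        if hits:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rows.append(np.nanmean(values[hits, :], axis=0))
        else:
            rows.append(np.full(n_samples, np.nan))
    out = pd.DataFrame(np.vstack(rows), index=pd.Index(gene_ids, name="gene_id"))
    out["n_probes"] = counts
    return out


@dataclass
class RankProductResult:
    """Per-gene, per-direction rank products with permutation pfp estimates."""

    table: pd.DataFrame  # columns: gene_id, direction, RP, rank, pfp
    n_comparisons: int
    n_permutations: int
    rng_seed: int

    def direction(self, direction: str) -> pd.DataFrame:
        return self.table.loc[self.table["direction"] == direction].reset_index(drop=True)


def _rank_product(ranks: np.ndarray) -> np.ndarray:
    """Geometric-mean rank across comparisons, computed in log space."""
    return np.exp(np.mean(np.log(ranks), axis=1))


def _null_rp_sorted(
    G: int, nA: int, nB: int, B: int, rng: np.random.Generator, offset: int = 0
) -> np.ndarray:
    """Sorted null RP values from B pseudo-datasets with crossed comparisons.

    Each pseudo-dataset draws i.i.d. standard-normal pseudo-replicates,
    forms the K = nA x nB crossed differences and ranks them, reproducing
    the rank correlation the shared replicates induce; the resulting rank
    law is distribution-free under exchangeable noise. ``offset`` shifts
    every null rank upward, modelling the displacement of null genes by
    that many confidently non-null genes ranking above them.
    """
    K = nA * nB
    null = np.empty((B, G))
    for b in range(B):
        u = rng.standard_normal((G, nA))
        v = rng.standard_normal((G, nB))
        log_sum = np.zeros(G)
        for i in range(nA):
            for j in range(nB):
                log_sum += np.log(rankdata(-(u[:, i] - v[:, j])) + offset)
        null[b] = np.exp(log_sum / K)
    return np.sort(null, axis=None)


def _pfp_from_null(rp: np.ndarray, null_sorted: np.ndarray, B: int) -> np.ndarray:
    """pfp = (expected null RPs at or below) / rank, cum-min smoothed."""
    position = rankdata(rp, method="ordinal").astype(int)
    expected = np.searchsorted(null_sorted, rp, side="right") / B
    pfp = expected / position
    order = np.argsort(position)
    pfp_sorted = np.minimum.accumulate(pfp[order][::-1])[::-1]
    out = np.empty_like(pfp)
    out[order] = pfp_sorted
    return out


def rank_product_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    gene_ids: np.ndarray | None = None,
    confident_pfp: float = 0.05,
    max_conditioning_passes: int = 4,
) -> RankProductResult:
    """Unpaired two-class Rank Product test (group A vs group B).

    ``group_a``/``group_b`` are (genes x replicates) matrices of per-gene
    log2 signals. Genes with any missing value are dropped listwise before
    ranking. Both directions are tested: ``up_in_complemented`` treats large
    A-minus-B differences as rank 1, ``down_in_complemented`` the reverse.

    The null pools ``n_permutations`` simulated datasets of crossed i.i.d.
    pseudo-replicate differences (see module docstring). The conditional
    passes re-estimate pfp with null ranks offset by the number of genes
    confidently called (pfp < ``confident_pfp``, discounted by the expected
    false fraction among them), iterating at most
    ``max_conditioning_passes`` times or until the confident count stops
    growing. Deterministic given ``seed``; with equal group sizes the same
    null sample serves both directions, making the test exactly
    antisymmetric under group swap.
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    Bm = np.atleast_2d(np.asarray(group_b, dtype=float))
    if A.shape[0] != Bm.shape[0]:
        raise ValueError("groups must cover the same genes")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    nA, nB = A.shape[1], Bm.shape[1]
    if nA < 1 or nB < 1:
        raise ValueError("each group needs at least one replicate")

    if gene_ids is None:
        gene_ids = np.arange(A.shape[0]).astype(str)
    gene_ids = np.asarray(gene_ids)

    complete = np.isfinite(A).all(axis=1) & np.isfinite(Bm).all(axis=1)
    A, Bm, gene_ids = A[complete], Bm[complete], gene_ids[complete]
    G = A.shape[0]
    if G < 2:
        raise ValueError(f"need at least 2 genes with complete data, got {G}")

    K = nA * nB
    diffs = np.empty((G, K))
    k = 0
    for i in range(nA):
        for j in range(nB):
            diffs[:, k] = A[:, i] - Bm[:, j]
            k += 1

    frames = []
    for direction, sign in ((DIR_UP, -1.0), (DIR_DOWN, 1.0)):
        ranks = np.column_stack(
            [rankdata(sign * diffs[:, k], method="average") for k in range(K)]
        )
        rp = _rank_product(ranks)
        position = rankdata(rp, method="ordinal").astype(int)  # 1..G, ties by order
        n_confident = 0
        for _ in range(max_conditioning_passes):
            rng = np.random.default_rng(seed)  # same draws; only the offset moves
            null_sorted = _null_rp_sorted(
                G - n_confident, nA, nB, n_permutations, rng, offset=n_confident
            )
            pfp_out = _pfp_from_null(rp, null_sorted, n_permutations)
            new_confident = int(np.floor((pfp_out < confident_pfp).sum() * (1 - confident_pfp)))
            if new_confident <= n_confident:
                break
            n_confident = new_confident
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "direction": direction,
                    "RP": rp,
                    "rank": position,
                    "pfp": pfp_out,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return RankProductResult(
        table=table, n_comparisons=K, n_permutations=n_permutations, rng_seed=seed
    )


def select_de(result: RankProductResult, pfp_cutoff: float = 0.15) -> dict[str, list[str]]:
    """Select differentially expressed genes at a strict pfp cutoff.

    A gene appears in at most one direction: the direction with the smaller
    pfp (ties broken by smaller RP, then toward up).
    """
    if not (0 < pfp_cutoff <= 1):
        raise ValueError(f"pfp_cutoff must be in (0, 1], got {pfp_cutoff}")
    up = result.direction(DIR_UP).set_index("gene_id")
    down = result.direction(DIR_DOWN).set_index("gene_id")
    up_list, down_list = [], []
    for gene in up.index:
        u, d = up.loc[gene], down.loc[gene]
        u_hit = u["pfp"] < pfp_cutoff
        d_hit = d["pfp"] < pfp_cutoff
        if u_hit and d_hit:
            if (u["pfp"], u["RP"]) <= (d["pfp"], d["RP"]):
                d_hit = False
            else:
                u_hit = False
        if u_hit:
            up_list.append(gene)
        elif d_hit:
            down_list.append(gene)
    return {"up": up_list, "down": down_list}


_ID_RE = re.compile(r"^([A-Za-z_]+)(\d+)$")


def _split_gene_id(gene_id: str) -> tuple[str, int]:
    m = _ID_RE.match(gene_id)
    if not m:
        raise ValueError(f"malformed gene id {gene_id!r}: expected alphabetic prefix + digits")
    return m.group(1), int(m.group(2))


def count_in_cluster(
    de_list: list[str],
    cluster_range: tuple[str, str],
    exclusions: set[str] | None = None,
) -> int:
    """Count listed genes whose id falls in an inclusive SCO-style range.

    ``cluster_range`` is (low_id, high_id), e.g. ("SCO3210", "SCO3249");
    ids in ``exclusions`` are never counted.
    """
    exclusions = exclusions or set()
    lo_prefix, lo_num = _split_gene_id(cluster_range[0])
    hi_prefix, hi_num = _split_gene_id(cluster_range[1])
    if lo_prefix != hi_prefix:
        raise ValueError(f"cluster range prefixes differ: {lo_prefix!r} vs {hi_prefix!r}")
    count = 0
    for gene in de_list:
        prefix, num = _split_gene_id(gene)
        if prefix == lo_prefix and lo_num <= num <= hi_num and gene not in exclusions:
            count += 1
    return count
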