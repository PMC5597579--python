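"""Metagene profiling, heatmap ordering, high/low gene classification and
gene-set overlap testing.

A metagene matrix rescales every gene body to a common number of columns
(length-weighted bin averaging) with fixed-width flanks on either side,
rows oriented 5'->3' regardless of strand.  Genes are split into "high"
and "low" classes by exact 1-D 2-means — a scan over all sorted-order
thresholds, which finds the global optimum of the within-cluster
sum-of-squares objective, so no initialization or seed can matter.
Overlap between two high sets is scored with the upper-tail
hypergeometric distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import BinnedTrack, GeneProfileMatrix, GenomeLayout


class DegenerateClusteringError(ValueError):
    """All scores identical; a 2-partition is meaningless."""


@dataclass(frozen=True)
class GeneSetOverlap:
    """Hypergeometric upper-tail overlap test between two gene sets drawn
    from a common universe."""

    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    p_value: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_a_size, self.set_b_size):
            raise ValueError("overlap exceeds a set size")
        if not (0 <= self.p_value <= 1):
            raise ValueError("p_value outside [0, 1]")


def _segment_mean(
    vec: np.ndarray, bin_width: int, chrom_len: int, a: float, b: float
) -> float:
    """Length-weighted mean of a binned signal over [a, b); NaN when the
    segment leaves the chromosome or is empty."""
    if b <= a:
        return float("nan")
    if a < 0 or b > chrom_len:
        return float("nan")
    first = int(math.floor(a / bin_width))
    last = int(math.ceil(b / bin_width))
    last = min(last, vec.size)
    idx = np.arange(first, last)
    starts = idx * bin_width
    ends = np.minimum(starts + bin_width, chrom_len)
    overlap = np.minimum(ends, b) - np.maximum(starts, a)
    overlap = np.clip(overlap, 0.0, None)
    total = overlap.sum()
    if total <= 0:
        return float("nan")
    return float(np.sum(vec[idx] * overlap) / total)


def metagene_matrix(
    track: BinnedTrack,
    layout: GenomeLayout,
    upstream: int = 500,
    downstream: int = 500,
    body_bins: int = 100,
) -> GeneProfileMatrix:
    """Build the genes x scaled-position matrix of a track.

    Each row runs 5'->3': ``upstream/bin_width`` fixed-width flank
    columns, ``body_bins`` scaled gene-body columns, then the downstream
    flank.  Flank columns use the track's bin width.  Minus-strand rows
    are computed in genomic order and reversed, so column 0 is always
    the upstream-most position.  Columns extending past a chromosome
    edge are missing (NaN); genes shorter than ``body_bins`` bp are
    still profiled (sub-bin column widths) and flagged in
    ``short_genes``.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("flank extents must be >= 0")
    if body_bins < 1:
        raise ValueError("body_bins must be >= 1")
    if not layout.genes:
        raise ValueError("layout has no genes")
    w = track.bin_width
    n_up = math.ceil(upstream / w) if upstream else 0
    n_down = math.ceil(downstream / w) if downstream else 0
    n_cols = n_up + body_bins + n_down
    sizes = layout.chrom_sizes

    rows = np.empty((len(layout.genes), n_cols))
    short: list[str] = []
    for r, gene in enumerate(layout.genes):
        vec = track.values[gene.chrom]
        chrom_len = sizes[gene.chrom]
        if gene.length < body_bins:
            short.append(gene.gene_id)
        # flank extents in genomic order depend on strand: the 5' flank
        # sits left of tss for '+' genes, right of tes for '-' genes
        if gene.strand == "+":
            left_n, left_w = n_up, w
            right_n, right_w = n_down, w
        else:
            left_n, left_w = n_down, w
            right_n, right_w = n_up, w
        bounds = np.concatenate(
            [
                gene.tss - left_w * np.arange(left_n, 0, -1),
                gene.tss + gene.length * np.arange(body_bins + 1) / body_bins,
                gene.tes + right_w * np.arange(1, right_n + 1),
            ]
        )
        row = np.array(
            [
                _segment_mean(vec, w, chrom_len, bounds[j], bounds[j + 1])
                for j in range(n_cols)
            ]
        )
        rows[r] = row[::-1] if gene.strand == "-" else row
    return GeneProfileMatrix(
        gene_ids=[g.gene_id for g in layout.genes],
        values=rows,
        n_upstream=n_up,
        n_body=body_bins,
        n_downstream=n_down,
        flank_bin_width=w,
        short_genes=short,
    )


def average_profile(m: GeneProfileMatrix) -> np.ndarray:
    """Column-wise mean profile over all genes, ignoring missing
    entries; an all-missing column stays NaN."""
    if len(m.gene_ids) == 0:
        raise ValueError("empty profile matrix")
    with np.errstate(invalid="ignore"):
        out = np.full(m.values.shape[1], np.nan)
        counts = np.sum(~np.isnan(m.values), axis=0)
        cols = counts > 0
        out[cols] = np.nanmean(m.values[:, cols], axis=0)
    return out


def heatmap_order(m: GeneProfileMatrix) -> list[str]:
    """Gene ids sorted descending by per-gene body-mean enrichment
    (stable; ties broken by lexicographic gene id)."""
    summary = m.summary
    if summary.isna().any():
        raise ValueError(
            "summary undefined for genes "
            f"{summary.index[summary.isna()].tolist()}"
        )
    df = summary.rename_axis("gene_id").reset_index()
    df = df.sort_values(
        ["body_mean", "gene_id"], ascending=[False, True], kind="stable"
    )
    return df["gene_id"].tolist()


def kmeans_high_low(
    scores: pd.Series | np.ndarray, seed: int | None = None
) -> tuple[set, set]:
    """Exact optimal 2-partition of 1-D scores into high/low classes.

    Scans all n−1 thresholds in sorted order and minimizes the
    within-cluster sum of squares; for 1-D data the optimal 2-means
    clusters are contiguous in sorted order, so this scan is exact and
    fully deterministic — ``seed`` is accepted for interface symmetry
    but has no effect.
    """
    if not isinstance(scores, pd.Series):
        scores = pd.Series(np.asarray(scores, dtype=float))
    values = scores.to_numpy(dtype=float)
    if values.size < 2 or np.unique(values).size < 2:
        raise DegenerateClusteringError(
            "need at least two distinct score values"
        )
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = x.size
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    ks = np.arange(1, n)  # low cluster = first k sorted values
    sum_lo, sum_hi = csum[ks - 1], csum[-1] - csum[ks - 1]
    sq_lo, sq_hi = csq[ks - 1], csq[-1] - csq[ks - 1]
    wcss = (sq_lo - sum_lo**2 / ks) + (sq_hi - sum_hi**2 / (n - ks))
    k_best = int(ks[np.argmin(wcss)])
    low_idx, high_idx = order[:k_best], order[k_best:]
    # by construction the upper block has the larger mean
    high = set(scores.index[high_idx])
    low = set(scores.index[low_idx])
    return high, low


def hypergeom_overlap(
    universe: set | list, set_a: set | list, set_b: set | list
) -> GeneSetOverlap:
    """Upper-tail hypergeometric p-value of the overlap between two gene
    sets: ``P(X >= |A ∩ B|)`` for X ~ Hypergeom(|U|, |A|, |B|)."""
    universe, set_a, set_b = set(universe), set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    m, a, b = len(universe), len(set_a), len(set_b)
    p = float(hypergeom.sf(k - 1, m, a, b))
    return GeneSetOverlap(
        universe_size=m, set_a_size=a, set_b_size=b, overlap=k,
        p_value=min(p, 1.0),
    )
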