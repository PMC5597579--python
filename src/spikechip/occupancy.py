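"""Normalized fold-change tracks and region-level fold enrichment.

Tracks are plain per-bin ratios, optionally scaled by a calibration
factor N (spike-in or SES derived) and optionally log2-transformed for
display.  The region statistic mirrors a qPCR-style readout: the
enrichment of a target region (e.g. the centromeric central core)
relative to a control locus, each summed with fractional-overlap
weighting and compared between IP and input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinnedTrack


class ZeroDenominatorError(ZeroDivisionError):
    """A ratio denominator is zero with no pseudocount; carries bins."""


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class RegionEnrichment:
    """Fold enrichment of a target region over a control region,
    (IP_target/IP_control) / (input_target/input_control)."""

    target_region: Interval
    control_region: Interval
    fold_enrichment: float
    replicate_values: list[float] = field(default_factory=list)

    @property
    def mean(self) -> float:
        if self.replicate_values:
            return float(np.mean(self.replicate_values))
        return self.fold_enrichment

    @property
    def sd(self) -> float:
        """Sample s.d. over replicates (NaN below two replicates)."""
        if len(self.replicate_values) >= 2:
            return float(np.std(self.replicate_values, ddof=1))
        return float("nan")


def _check_compatible(a: BinnedTrack, b: BinnedTrack) -> None:
    if a.bin_width != b.bin_width:
        raise ValueError("tracks have different bin widths")
    if a.layout.chromosomes != b.layout.chromosomes:
        raise ValueError("tracks are on different layouts")


def ratio_track(
    ip: BinnedTrack,
    input_: BinnedTrack,
    n_factor: float = 1.0,
    pseudocount: float = 0.0,
    log2: bool = False,
) -> BinnedTrack:
    """Per-bin fold change of IP versus input.

    ``value = (n_factor * ip + pseudocount) / (input + pseudocount)``,
    log2-transformed when requested.  With ``pseudocount = 0`` any
    zero-input bin is an error (the offending bins are listed) rather
    than an infinity.
    """
    _check_compatible(ip, input_)
    if n_factor <= 0:
        raise ValueError("n_factor must be > 0")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    out = {}
    for chrom, _ in ip.layout.chromosomes:
        num = n_factor * ip.values[chrom] + pseudocount
        den = input_.values[chrom] + pseudocount
        zero = np.flatnonzero(den == 0)
        if zero.size:
            raise ZeroDenominatorError(
                f"zero denominator with zero pseudocount on {chrom}, bins "
                f"{zero[:10].tolist()}{'...' if zero.size > 10 else ''}"
            )
        r = num / den
        out[chrom] = np.log2(r) if log2 else r
    return BinnedTrack(
        layout=ip.layout,
        bin_width=ip.bin_width,
        values=out,
        kind="ratio",
        log2=log2,
    )


def mutant_vs_wt_track(
    ip_mut: BinnedTrack,
    ip_wt: BinnedTrack,
    n_factor: float = 1.0,
    pseudocount: float = 0.0,
    log2: bool = False,
) -> BinnedTrack:
    """Per-bin fold change of the mutant IP versus the wild-type IP,
    scaled by the spike-in factor N so the ratio is calibrated in
    absolute occupancy units (wild type as denominator)."""
    return ratio_track(ip_mut, ip_wt, n_factor, pseudocount, log2)


def _interval_sum(track: BinnedTrack, region: Interval) -> float:
    """Sum of track signal over a region with fractional-overlap
    weighting of bins straddling the region edges."""
    if region.chrom not in track.values:
        raise ValueError(f"region on unknown chromosome {region.chrom}")
    chrom_len = track.layout.chrom_sizes[region.chrom]
    if region.end > chrom_len:
        raise ValueError("region extends past chromosome end")
    w = track.bin_width
    vec = track.values[region.chrom]
    first = region.start // w
    last = (region.end - 1) // w
    idx = np.arange(first, last + 1)
    bin_starts = idx * w
    bin_ends = np.minimum(bin_starts + w, chrom_len)
    overlap = np.minimum(bin_ends, region.end) - np.maximum(
        bin_starts, region.start
    )
    frac = overlap / (bin_ends - bin_starts)
    return float(np.sum(vec[idx] * frac))


def region_mean(track: BinnedTrack, region: Interval) -> float:
    """Length-weighted mean signal of a track over a region."""
    w = track.bin_width
    chrom_len = track.layout.chrom_sizes[region.chrom]
    first = region.start // w
    last = (region.end - 1) // w
    idx = np.arange(first, last + 1)
    bin_starts = idx * w
    bin_ends = np.minimum(bin_starts + w, chrom_len)
    overlap = np.minimum(bin_ends, region.end) - np.maximum(
        bin_starts, region.start
    )
    vec = track.values[region.chrom]
    return float(np.sum(vec[idx] * overlap) / overlap.sum())


def region_fold_enrichment(
    ip: BinnedTrack,
    input_: BinnedTrack,
    target: Interval,
    control: Interval,
) -> RegionEnrichment:
    """Fold enrichment of ``target`` over ``control``:
    ``(IP_t / IP_c) / (input_t / input_c)``.

    Depth-invariant: rescaling either whole library leaves it unchanged.
    Equals one whenever IP and input cover the two regions
    proportionally.
    """
    _check_compatible(ip, input_)
    ip_t = _interval_sum(ip, target)
    ip_c = _interval_sum(ip, control)
    in_t = _interval_sum(input_, target)
    in_c = _interval_sum(input_, control)
    if ip_c <= 0 or in_c <= 0:
        raise ZeroDenominatorError(
            "control region has zero IP or input signal"
        )
    if in_t <= 0:
        raise ZeroDenominatorError("target region has zero input signal")
    fe = (ip_t / ip_c) / (in_t / in_c)
    return RegionEnrichment(target, control, fe)


def replicate_enrichment(
    replicates: list[tuple[BinnedTrack, BinnedTrack]],
    target: Interval,
    control: Interval,
) -> RegionEnrichment:
    """Region fold enrichment over replicate (IP, input) pairs,
    reported as per-replicate values with mean and sample s.d."""
    if not replicates:
        raise ValueError("at least one replicate required")
    values = [
        region_fold_enrichment(ip, inp, target, control).fold_enrichment
        for ip, inp in replicates
    ]
    return RegionEnrichment(
        target, control, float(np.mean(values)), replicate_values=values
    )
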