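"""Shared domain types and readers/writers for the pipeline's text formats.

Coordinate convention: every interval in this package is 0-based,
half-open ``[start, end)`` — the BED convention.  Gene transcription
start/end sites are stored in genomic orientation (``tss < tes``) with
the strand kept separately; strand-aware positions are exposed as
properties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DOMAIN_LABELS = frozenset({"cnt", "imr", "otr", "euchromatin", "insert"})


class LayoutError(ValueError):
    """Raised when an annotation violates a layout invariant."""


class ParseError(ValueError):
    """Raised for a malformed annotation line; carries the line number."""


@dataclass(frozen=True)
class Domain:
    """A labelled chromosomal domain, e.g. a centromere sub-domain."""

    chrom: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise LayoutError(
                f"domain {self.chrom}:{self.start}-{self.end} is not a valid "
                "half-open interval"
            )
        if self.label not in DOMAIN_LABELS:
            raise LayoutError(
                f"unknown domain label {self.label!r}; expected one of "
                f"{sorted(DOMAIN_LABELS)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gene:
    """A gene model.  ``tss``/``tes`` are genomic start/end (tss < tes);
    for a minus-strand gene the biological 5' end is at ``tes``."""

    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise LayoutError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.tss < self.tes):
            raise LayoutError(
                f"gene {self.gene_id}: require 0 <= tss < tes, got "
                f"[{self.tss}, {self.tes})"
            )

    @property
    def length(self) -> int:
        return self.tes - self.tss

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the biological TSS."""
        return self.tss if self.strand == "+" else self.tes

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the biological TES."""
        return self.tes if self.strand == "+" else self.tss


@dataclass
class GenomeLayout:
    """Chromosome sizes plus domain and gene annotations.

    This is the coordinate frame every track and profile matrix shares.
    """

    chromosomes: list[tuple[str, int]]
    domains: list[Domain] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def validate(self) -> None:
        sizes = self.chrom_sizes
        if len(sizes) != len(self.chromosomes):
            raise LayoutError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise LayoutError(f"chromosome {name} has non-positive length")
        for d in self.domains:
            if d.chrom not in sizes:
                raise LayoutError(f"domain on unknown chromosome {d.chrom}")
            if d.end > sizes[d.chrom]:
                raise LayoutError(
                    f"domain {d.chrom}:{d.start}-{d.end} extends past "
                    f"chromosome end ({sizes[d.chrom]})"
                )
        # distinctly-labelled domains on one chromosome must not overlap
        by_chrom: dict[str, list[Domain]] = {}
        for d in self.domains:
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, ds in by_chrom.items():
            ds = sorted(ds, key=lambda d: (d.start, d.end))
            for a, b in zip(ds, ds[1:]):
                if b.start < a.end and a.label != b.label:
                    raise LayoutError(
                        f"domains {a.label} and {b.label} overlap on {chrom} "
                        f"at [{b.start}, {a.end})"
                    )
        seen_ids: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen_ids:
                raise LayoutError(f"duplicate gene id {g.gene_id}")
            seen_ids.add(g.gene_id)
            if g.chrom not in sizes:
                raise LayoutError(f"gene {g.gene_id} on unknown chromosome")
            if g.tes > sizes[g.chrom]:
                raise LayoutError(
                    f"gene {g.gene_id} extends past chromosome end"
                )

    def n_bins(self, bin_width: int) -> dict[str, int]:
        return {
            name: math.ceil(length / bin_width)
            for name, length in self.chromosomes
        }

    def domains_labelled(self, label: str) -> list[Domain]:
        return [d for d in self.domains if d.label == label]


@dataclass
class BinnedTrack:
    """Fixed-width per-bin signal on one genome layout.

    ``values`` maps chromosome name to a float vector with
    ``ceil(length / bin_width)`` entries; the last bin covers to the
    chromosome end.  Count-type tracks are non-negative; ratio-type
    tracks may carry any finite real and flag ``log2`` when on log scale.
    """

    layout: GenomeLayout
    bin_width: int
    values: dict[str, np.ndarray]
    kind: str = "count"  # "count" or "ratio"
    log2: bool = False

    def __post_init__(self) -> None:
        expected = self.layout.n_bins(self.bin_width)
        if set(self.values) != set(expected):
            raise ValueError(
                "track chromosomes do not match layout: "
                f"{sorted(self.values)} vs {sorted(expected)}"
            )
        for chrom, vec in self.values.items():
            vec = np.asarray(vec, dtype=float)
            self.values[chrom] = vec
            if vec.shape != (expected[chrom],):
                raise ValueError(
                    f"{chrom}: expected {expected[chrom]} bins, got {vec.shape}"
                )
            finite = np.isfinite(vec) | np.isnan(vec)
            if not finite.all():
                raise ValueError(f"{chrom}: track holds non-finite values")
            if self.kind == "count" and np.nanmin(vec, initial=0.0) < 0:
                raise ValueError(f"{chrom}: negative values in a count track")

    def total(self) -> float:
        return float(sum(np.nansum(v) for v in self.values.values()))

    def concat(self, chroms: Sequence[str] | None = None) -> np.ndarray:
        order = chroms if chroms is not None else [c for c, _ in self.layout.chromosomes]
        return np.concatenate([self.values[c] for c in order])

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            layout=self.layout,
            bin_width=self.bin_width,
            values={c: v.copy() for c, v in self.values.items()},
            kind=self.kind,
            log2=self.log2,
        )

    @classmethod
    def zeros(
        cls, layout: GenomeLayout, bin_width: int, kind: str = "count"
    ) -> "BinnedTrack":
        return cls(
            layout=layout,
            bin_width=bin_width,
            values={
                c: np.zeros(n) for c, n in layout.n_bins(bin_width).items()
            },
            kind=kind,
        )


@dataclass(frozen=True)
class SpikeInCounts:
    """The four read totals feeding spike-in calibration: IP and input
    libraries split by the genome (experimental vs spike-in) each read
    maps to."""

    ip_exp: int
    input_exp: int
    ip_spike: int
    input_spike: int

    def __post_init__(self) -> None:
        for name in ("ip_exp", "input_exp", "ip_spike", "input_spike"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")


@dataclass
class GeneProfileMatrix:
    """Genes x scaled-position signal matrix.

    Columns run 5'->3': ``n_upstream`` fixed-width flank bins, then
    ``n_body`` scaled gene-body bins, then ``n_downstream`` flank bins.
    ``summary`` is the per-gene mean over body columns (NaN-aware).
    """

    gene_ids: list[str]
    values: np.ndarray
    n_upstream: int
    n_body: int
    n_downstream: int
    flank_bin_width: int
    short_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_cols = self.n_upstream + self.n_body + self.n_downstream
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), n_cols):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {n_cols} columns"
            )

    @property
    def body_slice(self) -> slice:
        return slice(self.n_upstream, self.n_upstream + self.n_body)

    @property
    def summary(self) -> pd.Series:
        body = self.values[:, self.body_slice]
        with np.errstate(invalid="ignore"):
            means = np.nanmean(body, axis=1)
        return pd.Series(means, index=self.gene_ids, name="body_mean")

    def to_frame(self) -> pd.DataFrame:
        cols = (
            [f"up{i}" for i in range(self.n_upstream)]
            + [f"body{i}" for i in range(self.n_body)]
            + [f"down{i}" for i in range(self.n_downstream)]
        )
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)


@dataclass(frozen=True)
class LossAssayObservation:
    """One colony of the minichromosome loss assay: initial and final
    percentages of minichromosome-containing cells over N divisions."""

    colony_id: str
    initial_pct: float
    final_pct: float
    n_divisions: int
    n_cells_scored: int

    def __post_init__(self) -> None:
        if not (0 < self.initial_pct <= 100):
            raise ValueError("initial_pct must be in (0, 100]")
        if not (0 <= self.final_pct <= 100):
            raise ValueError("final_pct must be in [0, 100]")
        if self.n_divisions < 1:
            raise ValueError("n_divisions must be a positive integer")
        if self.n_cells_scored < 1:
            raise ValueError("n_cells_scored must be a positive integer")


# ---------------------------------------------------------------------------
# Readers / writers (plain text, deterministic)
# ---------------------------------------------------------------------------


def read_layout(
    domains_path: str | Path | None,
    genes_path: str | Path | None,
    chrom_sizes: dict[str, int] | str | Path,
) -> GenomeLayout:
    """Assemble a :class:`GenomeLayout` from BED-like annotation files.

    ``chrom_sizes`` is either a mapping or a two-column TSV
    (``chrom<TAB>length``).  Domains use 4 columns
    (chrom/start/end/label), genes 6 (chrom/start/end/id/score/strand).
    Coordinates are taken verbatim as 0-based half-open.
    """
    if not isinstance(chrom_sizes, dict):
        chrom_sizes = dict(
            pd.read_csv(
                chrom_sizes, sep="\t", header=None, names=["chrom", "length"]
            ).itertuples(index=False, name=None)
        )
    domains = read_domains_bed(domains_path) if domains_path else []
    genes = read_genes_bed(genes_path) if genes_path else []
    return GenomeLayout(
        chromosomes=sorted(chrom_sizes.items()), domains=domains, genes=genes
    )


def _bed_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_domains_bed(path: str | Path) -> list[Domain]:
    """Parse a 4-column BED of labelled domains (cnt/imr/otr/...)."""
    domains = []
    for lineno, fields in _bed_lines(path):
        if len(fields) < 4:
            raise ParseError(
                f"{path}:{lineno}: expected 4 columns chrom/start/end/label, "
                f"got {len(fields)}"
            )
        chrom, start, end, label = fields[:4]
        try:
            domains.append(Domain(chrom, int(start), int(end), label))
        except (ValueError, LayoutError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return domains


def read_genes_bed(path: str | Path) -> list[Gene]:
    """Parse a 6-column BED of gene models (chrom/start/end/id/score/strand)."""
    genes = []
    for lineno, fields in _bed_lines(path):
        if len(fields) < 6:
            raise ParseError(
                f"{path}:{lineno}: expected 6 columns "
                f"chrom/start/end/id/score/strand, got {len(fields)}"
            )
        chrom, start, end, gene_id, _score, strand = fields[:6]
        try:
            genes.append(Gene(gene_id, chrom, int(start), int(end), strand))
        except (ValueError, LayoutError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_domains_bed(domains: Sequence[Domain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.label}\n")


def write_genes_bed(genes: Sequence[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.tss}\t{g.tes}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def write_track(track: BinnedTrack, path: str | Path) -> None:
    """Write a track as 4-column bedGraph, merging runs of equal values.

    The run-length merge loses nothing: reading back with
    :func:`read_track` reproduces the per-bin values exactly.
    """
    sizes = track.layout.chrom_sizes
    with open(path, "w") as fh:
        for chrom, _ in track.layout.chromosomes:
            vec = track.values[chrom]
            if vec.size == 0:
                continue
            chrom_len = sizes[chrom]
            run_start = 0
            run_value = vec[0]
            for i in range(1, vec.size):
                if vec[i] != run_value and not (
                    np.isnan(vec[i]) and np.isnan(run_value)
                ):
                    end = min(i * track.bin_width, chrom_len)
                    fh.write(
                        f"{chrom}\t{run_start * track.bin_width}\t{end}"
                        f"\t{run_value:.10g}\n"
                    )
                    run_start, run_value = i, vec[i]
            fh.write(
                f"{chrom}\t{run_start * track.bin_width}\t{chrom_len}"
                f"\t{run_value:.10g}\n"
            )


def read_track(
    path: str | Path,
    layout: GenomeLayout,
    bin_width: int,
    kind: str = "count",
    log2: bool = False,
) -> BinnedTrack:
    """Read a bedGraph written on ``layout``'s bin grid back into a track.

    Intervals must align to ``bin_width`` boundaries (the final interval
    of a chromosome may end at the chromosome end).
    """
    track = BinnedTrack.zeros(layout, bin_width, kind="ratio")
    sizes = layout.chrom_sizes
    for lineno, fields in _bed_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom, start_s, end_s, value_s = fields[:4]
        if chrom not in sizes:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom}")
        start, end, value = int(start_s), int(end_s), float(value_s)
        if start % bin_width != 0 or (end % bin_width != 0 and end != sizes[chrom]):
            raise ParseError(
                f"{path}:{lineno}: interval [{start},{end}) not aligned to "
                f"{bin_width} bp bins"
            )
        first = start // bin_width
        last = math.ceil(end / bin_width)
        track.values[chrom][first:last] = value
    track.kind = kind
    track.log2 = log2
    if kind == "count":
        for chrom, vec in track.values.items():
            if np.nanmin(vec, initial=0.0) < 0:
                raise ParseError(f"{path}: negative values in a count track")
    return track


def read_spikein_counts_tsv(path: str | Path) -> dict[str, SpikeInCounts]:
    """Read a TSV of per-sample genome-split read totals.

    Columns: sample, ip_exp, input_exp, ip_spike, input_spike.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "ip_exp", "input_exp", "ip_spike", "input_spike"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return {
        row["sample"]: SpikeInCounts(
            int(row["ip_exp"]),
            int(row["input_exp"]),
            int(row["ip_spike"]),
            int(row["input_spike"]),
        )
        for _, row in df.iterrows()
    }


def write_spikein_counts_tsv(
    counts: dict[str, SpikeInCounts], path: str | Path
) -> None:
    rows = [
        {
            "sample": name,
            "ip_exp": c.ip_exp,
            "input_exp": c.input_exp,
            "ip_spike": c.ip_spike,
            "input_spike": c.input_spike,
        }
        for name, c in counts.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_loss_assay_tsv(path: str | Path) -> list[LossAssayObservation]:
    """Read colony observations: colony_id, initial_pct, final_pct,
    n_divisions, n_cells_scored (TSV with header, optional `strain`)."""
    df = pd.read_csv(path, sep="\t")
    return [
        LossAssayObservation(
            colony_id=str(row["colony_id"]),
            initial_pct=float(row["initial_pct"]),
            final_pct=float(row["final_pct"]),
            n_divisions=int(row["n_divisions"]),
            n_cells_scored=int(row["n_cells_scored"]),
        )
        for _, row in df.iterrows()
    ]


def write_loss_assay_tsv(
    observations: Sequence[LossAssayObservation], path: str | Path
) -> None:
    rows = [
        {
            "colony_id": o.colony_id,
            "initial_pct": o.initial_pct,
            "final_pct": o.final_pct,
            "n_divisions": o.n_divisions,
            "n_cells_scored": o.n_cells_scored,
        }
        for o in observations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
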