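"""Dual-genome ChIP read simulator and loss-assay colony generator.

The simulator emulates the statistical structure the downstream analysis
assumes, not the sequencing process: cells of an experimental genome are
mixed with spike-in cells at a fixed ratio before lysis, input reads fall
on bins in proportion to total (mix-weighted) chromatin, and IP reads in
proportion to the pulled-down target's occupancy times a capture
efficiency.  Read allocation is multinomial over bins; fragment lengths,
GC bias, mappability and duplicates are deliberately out of scope because
the analysis operates on binned counts.

An *expectation mode* bypasses sampling and returns the exact expected
counts, so every analytic identity of the normalization algebra can be
tested without Monte-Carlo error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BinnedTrack,
    Domain,
    Gene,
    GenomeLayout,
    LossAssayObservation,
    SpikeInCounts,
)

TARGETS = ("H3", "CENP-A", "H2A.Z", "Ies6")


class SimulationError(ValueError):
    """Raised for invalid simulator configurations."""


@dataclass(frozen=True)
class ExpectedSpikeInCounts:
    """Expectation-mode analogue of :class:`SpikeInCounts` (real-valued)."""

    ip_exp: float
    input_exp: float
    ip_spike: float
    input_spike: float


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplies one target's occupancy by ``factor`` on a named bin set
    (experimental genome only)."""

    condition: str
    target: str
    bins: dict[str, np.ndarray]  # chrom -> integer bin indices
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise SimulationError("condition-effect factor must be > 0")


@dataclass
class OccupancyModel:
    """Per-bin occupancy of each ChIP target on the experimental and
    spike-in genomes, plus condition-dependent multiplicative effects."""

    layout: GenomeLayout
    spike_layout: GenomeLayout
    bin_width: int
    baseline: dict[str, dict[str, np.ndarray]]
    spike_baseline: dict[str, dict[str, np.ndarray]]
    ip_efficiency: dict[str, float]
    condition_effects: list[ConditionEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, genome_layout, occ in (
            ("baseline", self.layout, self.baseline),
            ("spike_baseline", self.spike_layout, self.spike_baseline),
        ):
            nbins = genome_layout.n_bins(self.bin_width)
            for target, per_chrom in occ.items():
                for chrom, vec in per_chrom.items():
                    vec = np.asarray(vec, dtype=float)
                    per_chrom[chrom] = vec
                    if vec.shape != (nbins[chrom],):
                        raise SimulationError(
                            f"{name}[{target}][{chrom}]: wrong bin count"
                        )
                    if not np.isfinite(vec).all() or (vec < 0).any():
                        raise SimulationError(
                            f"{name}[{target}][{chrom}]: occupancies must be "
                            "finite and >= 0"
                        )
        for target, eff in self.ip_efficiency.items():
            if not (0 < eff <= 1):
                raise SimulationError(
                    f"ip_efficiency[{target}] must be in (0, 1]"
                )

    def occupancy(
        self, target: str, condition: str
    ) -> dict[str, np.ndarray]:
        """Experimental-genome occupancy of ``target`` under ``condition``."""
        occ = {c: v.copy() for c, v in self.baseline[target].items()}
        for eff in self.condition_effects:
            if eff.condition == condition and eff.target == target:
                for chrom, idx in eff.bins.items():
                    occ[chrom][idx] *= eff.factor
        return occ

    def chromatin(self) -> dict[str, np.ndarray]:
        """Total chromatin per bin driving input-read allocation (sum of
        baseline occupancies).  Condition-independent: the input library
        samples sonicated DNA, whose per-bin content does not change
        when a remodeler mutant redistributes one histone."""
        total = {
            c: np.zeros(n) for c, n in self.layout.n_bins(self.bin_width).items()
        }
        for target in self.baseline:
            for c, v in self.baseline[target].items():
                total[c] += v
        return total

    def spike_chromatin(self) -> dict[str, np.ndarray]:
        total = {
            c: np.zeros(n)
            for c, n in self.spike_layout.n_bins(self.bin_width).items()
        }
        for target in self.spike_baseline:
            for c, v in self.spike_baseline[target].items():
                total[c] += v
        return total


@dataclass(frozen=True)
class SimulationConfig:
    """Sequencing-scale parameters of one simulated ChIP experiment."""

    seed: int | None
    total_ip_reads: int = 1_000_000
    total_input_reads: int = 1_000_000
    mix_ratio: float = 1 / 8  # spike-in cells per experimental cell
    conditions: tuple[str, ...] = ("wt",)
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.total_ip_reads <= 0 or self.total_input_reads <= 0:
            raise SimulationError("read totals must be positive")
        if self.mix_ratio <= 0:
            raise SimulationError("mix_ratio must be > 0")


@dataclass
class ChipSimResult:
    """Tracks and genome-split totals of one simulated ChIP experiment."""

    counts: SpikeInCounts | ExpectedSpikeInCounts
    ip_exp: BinnedTrack
    input_exp: BinnedTrack
    ip_spike: BinnedTrack
    input_spike: BinnedTrack


def _flatten(
    layout: GenomeLayout, per_chrom: dict[str, np.ndarray]
) -> np.ndarray:
    return np.concatenate([per_chrom[c] for c, _ in layout.chromosomes])


def _unflatten(
    layout: GenomeLayout, bin_width: int, flat: np.ndarray
) -> dict[str, np.ndarray]:
    out = {}
    offset = 0
    for chrom, n in layout.n_bins(bin_width).items():
        out[chrom] = np.asarray(flat[offset : offset + n], dtype=float)
        offset += n
    return out


def _allocate(
    rng: np.random.Generator | None,
    total: int,
    weights: np.ndarray,
    expectation: bool,
) -> np.ndarray:
    s = weights.sum()
    if s <= 0:
        raise SimulationError("zero total occupancy for the sampled library")
    p = weights / s
    if expectation:
        return total * p
    if rng is None:
        raise SimulationError(
            "sampling requires an explicit seed; pass SimulationConfig(seed=...)"
        )
    return rng.multinomial(total, p).astype(float)


def simulate_chip(
    model: OccupancyModel,
    cfg: SimulationConfig,
    condition: str,
    target: str = "H3",
    expectation: bool = False,
    rng: np.random.Generator | None = None,
) -> ChipSimResult:
    """Simulate one IP/input library pair over the two-genome mixture.

    Input reads are allocated across the experimental and spike-in
    genomes in proportion to mix-weighted total chromatin, then across
    bins in proportion to per-bin chromatin.  IP reads follow the target
    occupancy times its capture efficiency, mix-weighted the same way.
    In expectation mode counts are exact expectations (real-valued);
    otherwise both libraries are multinomial draws under ``cfg.seed``.

    Returned :class:`SpikeInCounts` equal the column sums of the
    returned tracks by construction.
    """
    if target not in model.baseline:
        raise SimulationError(f"unknown target {target!r}")
    if rng is None and not expectation:
        if cfg.seed is None:
            raise SimulationError(
                "sampling requires an explicit seed; got SimulationConfig(seed=None)"
            )
        rng = np.random.default_rng(cfg.seed)

    eff = model.ip_efficiency.get(target, 1.0)
    occ_exp = _flatten(model.layout, model.occupancy(target, condition))
    occ_spike = _flatten(model.spike_layout, model.spike_baseline[target])
    if occ_exp.sum() <= 0 or occ_spike.sum() <= 0:
        raise SimulationError(
            f"target {target!r} has zero total occupancy on one genome"
        )
    chrom_exp = _flatten(model.layout, model.chromatin())
    chrom_spike = _flatten(model.spike_layout, model.spike_chromatin())

    w_exp, w_spike = 1.0, cfg.mix_ratio
    n_exp = occ_exp.size

    input_w = np.concatenate([w_exp * chrom_exp, w_spike * chrom_spike])
    ip_w = np.concatenate([w_exp * eff * occ_exp, w_spike * eff * occ_spike])

    input_reads = _allocate(rng, cfg.total_input_reads, input_w, expectation)
    ip_reads = _allocate(rng, cfg.total_ip_reads, ip_w, expectation)

    def track(layout, flat):
        return BinnedTrack(
            layout=layout,
            bin_width=model.bin_width,
            values=_unflatten(layout, model.bin_width, flat),
            kind="count",
        )

    ip_exp_t = track(model.layout, ip_reads[:n_exp])
    ip_spike_t = track(model.spike_layout, ip_reads[n_exp:])
    input_exp_t = track(model.layout, input_reads[:n_exp])
    input_spike_t = track(model.spike_layout, input_reads[n_exp:])

    totals = (
        ip_reads[:n_exp].sum(),
        input_reads[:n_exp].sum(),
        ip_reads[n_exp:].sum(),
        input_reads[n_exp:].sum(),
    )
    if expectation:
        counts: SpikeInCounts | ExpectedSpikeInCounts = ExpectedSpikeInCounts(
            *totals
        )
    else:
        counts = SpikeInCounts(*(int(round(t)) for t in totals))
    return ChipSimResult(counts, ip_exp_t, input_exp_t, ip_spike_t, input_spike_t)


# ---------------------------------------------------------------------------
# Study-shaped default model
# ---------------------------------------------------------------------------


def demo_layout(
    n_chromosomes: int = 3,
    chrom_length: int = 120_000,
    gene_length: int = 1_500,
    gene_gap: int = 500,
) -> GenomeLayout:
    """A scaled-down fission-yeast-like genome.

    Each chromosome carries a regional centromere at its midpoint —
    a central core (cnt, 4 kb) flanked by innermost repeats (imr, 3 kb
    each) and outer repeats (otr, 10 kb each) — with gene-dense
    euchromatic arms tiled by fixed-length genes of alternating strand.
    """
    cnt_half, imr_w, otr_w = 2_000, 3_000, 10_000
    chroms, domains, genes = [], [], []
    for i in range(1, n_chromosomes + 1):
        chrom = f"chr{i}"
        chroms.append((chrom, chrom_length))
        mid = chrom_length // 2
        cnt = (mid - cnt_half, mid + cnt_half)
        domains += [
            Domain(chrom, cnt[0], cnt[1], "cnt"),
            Domain(chrom, cnt[0] - imr_w, cnt[0], "imr"),
            Domain(chrom, cnt[1], cnt[1] + imr_w, "imr"),
            Domain(chrom, cnt[0] - imr_w - otr_w, cnt[0] - imr_w, "otr"),
            Domain(chrom, cnt[1] + imr_w, cnt[1] + imr_w + otr_w, "otr"),
        ]
        cen_start = cnt[0] - imr_w - otr_w
        cen_end = cnt[1] + imr_w + otr_w
        step = gene_length + gene_gap
        k = 0
        for arm_start, arm_end in ((0, cen_start), (cen_end, chrom_length)):
            pos = arm_start + gene_gap
            while pos + gene_length <= arm_end:
                strand = "+" if k % 2 == 0 else "-"
                genes.append(
                    Gene(f"{chrom}_g{k:03d}", chrom, pos, pos + gene_length, strand)
                )
                pos += step
                k += 1
    return GenomeLayout(chromosomes=chroms, domains=domains, genes=genes)


def spike_demo_layout(length: int = 60_000) -> GenomeLayout:
    """Single-chromosome spike-in genome with no annotation."""
    return GenomeLayout(chromosomes=[("spike_I", length)])


def bins_overlapping(
    layout: GenomeLayout, bin_width: int, chrom: str, start: int, end: int
) -> np.ndarray:
    """Indices of bins overlapping ``[start, end)`` on ``chrom``."""
    n = layout.n_bins(bin_width)[chrom]
    first = max(start // bin_width, 0)
    last = min(math.ceil(end / bin_width), n)
    return np.arange(first, last)


@dataclass
class StudyDesign:
    """The default simulated study: an occupancy model, the set of
    remodeler-bound genes, and the bound bins the mutant effect targets."""

    model: OccupancyModel
    bound_genes: list[str]
    bound_bins: dict[str, np.ndarray]
    unbound_bins: dict[str, np.ndarray]


def build_study_model(
    layout: GenomeLayout | None = None,
    bin_width: int = 50,
    h3_fold_change: float = 1.5,
    mutant_condition: str = "ies6D",
    bound_gene_stride: int = 3,
) -> StudyDesign:
    """Construct the default occupancy model of the simulated study.

    Occupancy structure: histone H3 covers the genome but is depleted in
    the central core where CENP-A nucleosomes dominate; CENP-A
    enrichment is confined to cnt (10x over its low background);
    the Ino80 subunit (Ies6) binds the central kinetochore domain and a
    designated subset of genes (every ``bound_gene_stride``-th gene).
    The mutant condition multiplies H3 occupancy by ``h3_fold_change``
    on exactly those remodeler-bound bins, emulating failed H3 removal.
    The spike-in genome is uniform and condition-independent.
    """
    layout = layout if layout is not None else demo_layout()
    spike = spike_demo_layout()
    nbins = layout.n_bins(bin_width)
    chroms = [c for c, _ in layout.chromosomes]

    def uniform(value: float) -> dict[str, np.ndarray]:
        return {c: np.full(nbins[c], value) for c in chroms}

    h3 = uniform(1.0)
    cenpa = uniform(0.1)
    h2az = uniform(0.3)
    ies6 = uniform(0.1)

    for d in layout.domains_labelled("cnt"):
        idx = bins_overlapping(layout, bin_width, d.chrom, d.start, d.end)
        h3[d.chrom][idx] = 0.3
        cenpa[d.chrom][idx] = 1.0
        ies6[d.chrom][idx] = 1.0
    for d in layout.domains_labelled("imr"):
        idx = bins_overlapping(layout, bin_width, d.chrom, d.start, d.end)
        ies6[d.chrom][idx] = 0.7

    bound_genes = [
        g.gene_id for i, g in enumerate(layout.genes) if i % bound_gene_stride == 0
    ]
    bound_set = set(bound_genes)
    bound_bins = {c: [] for c in chroms}
    for g in layout.genes:
        if g.gene_id in bound_set:
            idx = bins_overlapping(layout, bin_width, g.chrom, g.tss, g.tes)
            ies6[g.chrom][idx] = 1.0
            bound_bins[g.chrom].append(idx)
    bound_bins = {
        c: np.unique(np.concatenate(v)) if v else np.array([], dtype=int)
        for c, v in bound_bins.items()
    }
    # unbound control bins: bodies of the genes NOT designated bound
    unbound_bins = {c: [] for c in chroms}
    for g in layout.genes:
        if g.gene_id not in bound_set:
            unbound_bins[g.chrom].append(
                bins_overlapping(layout, bin_width, g.chrom, g.tss, g.tes)
            )
    unbound_bins = {
        c: np.unique(np.concatenate(v)) if v else np.array([], dtype=int)
        for c, v in unbound_bins.items()
    }

    spike_nbins = spike.n_bins(bin_width)
    spike_uniform = lambda v: {
        c: np.full(n, v) for c, n in spike_nbins.items()
    }
    model = OccupancyModel(
        layout=layout,
        spike_layout=spike,
        bin_width=bin_width,
        baseline={"H3": h3, "CENP-A": cenpa, "H2A.Z": h2az, "Ies6": ies6},
        spike_baseline={
            "H3": spike_uniform(1.0),
            "CENP-A": spike_uniform(0.5),
            "H2A.Z": spike_uniform(0.5),
            "Ies6": spike_uniform(0.5),
        },
        ip_efficiency={"H3": 0.8, "CENP-A": 0.5, "H2A.Z": 0.5, "Ies6": 0.5},
        condition_effects=[
            ConditionEffect(mutant_condition, "H3", bound_bins, h3_fold_change)
        ],
    )
    return StudyDesign(model, bound_genes, bound_bins, unbound_bins)


# ---------------------------------------------------------------------------
# Minichromosome loss assay
# ---------------------------------------------------------------------------


def simulate_loss_assay(
    p_loss: float,
    n_divisions: int,
    initial_pct: float,
    colonies: int,
    n_cells: int,
    seed: int | None,
    expectation: bool = False,
) -> list[LossAssayObservation]:
    """Simulate marker-retention scoring of ``colonies`` colonies.

    Each colony's true final retention is ``I * (1 - p_loss)**N``
    (geometric per-division loss); the scored retention is binomial over
    ``n_cells`` cells at that proportion.  Expectation mode reports the
    true retention exactly, making the estimator's inversion testable
    without sampling noise.
    """
    if not (0 <= p_loss < 1):
        raise SimulationError("p_loss must be in [0, 1)")
    if n_divisions < 1:
        raise SimulationError("n_divisions must be >= 1")
    if initial_pct <= 0:
        raise SimulationError("initial_pct must be > 0")
    if not expectation and seed is None:
        raise SimulationError("sampling requires an explicit seed")
    rng = np.random.default_rng(seed) if not expectation else None
    true_final = initial_pct * (1.0 - p_loss) ** n_divisions
    out = []
    for i in range(colonies):
        if expectation:
            final = true_final
        else:
            final = 100.0 * rng.binomial(n_cells, true_final / 100.0) / n_cells
        out.append(
            LossAssayObservation(
                colony_id=f"colony{i + 1}",
                initial_pct=initial_pct,
                final_pct=final,
                n_divisions=n_divisions,
                n_cells_scored=n_cells,
            )
        )
    return out
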