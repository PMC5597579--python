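# Methods

This package re-implements, as a tested pipeline over simulated data,
the quantitative analysis used to study how an ATP-dependent chromatin
remodeler (the Ino80 complex) removes histone H3 from fission-yeast
centromeres to make room for the centromeric histone variant CENP-A.
Because the original sequencing libraries are not part of this artifact,
every stage runs against a dual-genome read simulator whose structure
matches the assumptions of the analysis; all quantitative guarantees in
the test suite are therefore statements about the method, exercised on
data whose ground truth is known exactly.

## Spike-in (ChIP-Rx) calibration

ChIP-seq coverage is internally normalized per library, so a genome-wide
change in the pulled-down histone (the signature of a remodeler mutant)
is invisible in ordinary IP/input ratios. The calibration adds a fixed
admixture of foreign cells — one spike-in cell per eight experimental
cells for H3 — before lysis, so every library carries an internal
constant. With read totals split by genome, the normalized IP/input
ratio is

    E^IP = (IP_exp / input_exp) / (IP_spike / input_spike)

and the browser-scale factor `N` solves `N · IP/input = E^IP` within a
sample, or `N · IP_mut/IP_wt = E^IP_mut / E^IP_wt` between conditions.
`E^IP` is invariant to sequencing depth of either library and linear in
the true recovery of the experimental genome, which is what makes the
mutant-vs-wt contrast absolute. Read totals enter raw: no length or GC
correction, no pseudocounts — a zero spike-in denominator is an error,
not a value, because calibration without spike-in signal is meaningless.

## SES scaling

Targets assayed without spike-in (CENP-A, Iec1, Ies6) are normalized by
signal extraction scaling. The method is specified operationally here:
sort bins ascending by IP signal, find the cut maximizing the gap
between the cumulative input fraction and the cumulative IP fraction
(first maximum on ties — the most conservative background), call bins
below the cut background, and scale the input track by
`(background IP / total IP) / (background input / total input)` before
ratio formation. The scale is applied to the input (rather than the IP)
track; the alternative differs only by a global inversion. The
implementation is checked against an exhaustive cut-point search.

## Fold-change tracks and region enrichment

Ratio tracks are plain per-bin quotients `(N·IP + c) / (input + c)`.
The pseudocount `c` defaults to 1 read for browser-style tracks and to 0
(strict: zero denominators raise) for region statistics. The
qPCR-style region readout is
`(IP_target/IP_control) / (input_target/input_control)` with
fractional-overlap weighting for bins straddling region edges; it is
invariant to depth rescaling of either library. Linear scale is
canonical; log2 is a display flag.

## Metagene profiling and gene classification

Each gene is profiled from −0.5 kb of the TSS to +0.5 kb of the TES:
fixed-width flank columns at the track's bin width (50 bp default), the
gene body rescaled to 100 columns by length-weighted averaging of
overlapping bins, minus-strand rows reversed so column 0 is always the
5′ end. Columns leaving the chromosome are missing (NaN) and excluded
from means; genes shorter than one body column per bp are profiled with
sub-bin column widths and flagged. The per-gene score fed to ordering
and clustering is the mean over body columns (the summary statistic was
an open choice; the body mean is the simplest one consistent with
scaled-region heatmaps).

High/low classification uses 2-means in one dimension, solved exactly:
the optimal clusters of 1-D k-means are contiguous in sorted order, so a
scan over the n−1 sorted-order thresholds with prefix sums finds the
global within-cluster sum-of-squares optimum. This removes the
initialization and seed sensitivity of iterative k-means entirely — the
`seed` argument exists for interface symmetry and has no effect.
Overlap between two high sets is tested with the upper-tail
hypergeometric distribution, `P(X ≥ k)`, computed via the log-space
survival function and verified against exact binomial-coefficient
enumeration in the tests.

## Minichromosome loss rate

Retention of a non-essential minichromosome over `N` non-selective
divisions follows a geometric model; the estimator inverts it:

    loss rate per division (%) = 100 · (1 − (F/I)^(1/N))

where `I` and `F` are the initial and final percentages of
minichromosome-containing cells. Replicate colonies are estimated
individually and aggregated as mean ± sample s.d. (n−1); pooled-count
estimation would weight colonies by cells scored, which the per-colony
reading avoids. `F = 0` leaves the formula undefined and is reported as
a flagged 100 % sentinel; `F > I` (scoring noise) yields a flagged
negative rate. `N` is a per-experiment input (default 11 for
simulations, the middle of the 10–12 divisions such assays run).

## The simulator

The generator emulates exactly the statistics the analysis consumes and
nothing below them. A scaled-down genome (three 120-kb chromosomes,
each with a regional centromere: 4-kb central core `cnt`, 3-kb
innermost repeats `imr`, 10-kb outer repeats `otr`, arms tiled by
1.5-kb genes) carries per-bin occupancies for H3, CENP-A, H2A.Z and the
Ino80 subunit Ies6 at 50-bp bins: H3 genome-wide but depleted in `cnt`,
CENP-A at 10× background only in `cnt`, Ies6 on the central kinetochore
domain and on a designated third of genes ("remodeler-bound"). The
mutant condition multiplies H3 occupancy by 1.5 on exactly the bound
bins, emulating failed H3 removal. The spike-in genome is a single
uniform 60-kb chromosome — an independent calibration reference, not a
reproduction of the budding-yeast genome.

Reads are allocated multinomially: input reads across the two genomes
by mix-weighted total chromatin and across bins by per-bin chromatin;
IP reads by target occupancy × capture efficiency, mix-weighted the
same way. Input allocation is condition-independent (it samples
sonicated DNA content, which a histone redistribution does not change);
this choice also makes the spike-calibrated mutant/wt ratio equal the
simulated fold change exactly at infinite depth, which the tests
exploit. An expectation mode skips sampling and returns exact expected
counts so analytic identities are testable to 1e-12. Fragment lengths,
GC bias, mappability, duplicates and sequence-level reads are
deliberately out of scope: the analysis operates on binned counts, so
passing tests demonstrate correctness of the quantitative pipeline, not
robustness to alignment artifacts in real libraries.

Sampling without an explicit seed is an error everywhere; there are no
silent default seeds.

## Problem sizes and numerics

Default simulations use 1,000,000 reads per library (pipeline demo:
200,000), 7,200 experimental + 1,200 spike-in bins, 132 genes, and
2,000 cells scored per loss-assay colony with 3 colonies per strain —
sizes chosen so a full study simulates in seconds while Monte-Carlo
error stays well inside the tested tolerances (fold-change recovery to
±0.1, loss-rate recovery to ±0.2 percentage points over 1,000
colonies). Bin width (50 bp) and track pseudocounts are configurable;
ties in SES and in the threshold scan break toward the smaller index;
heatmap ordering breaks score ties lexicographically by gene id.
bedGraph is the canonical track format (text, diffable); writers merge
equal-value runs and readers restore per-bin vectors exactly.

## Limitations

The simulator's uniform gene lengths and two-level occupancy make
classification unrealistically clean; real enrichment distributions are
continuous, and k-means high/low splits of them are sensitive to the
score distribution's shape in ways these tests do not probe. Region
enrichment values depend on total-chromatin composition at the target
region (the input is not uniform), so the "10× CENP-A" design value
appears as ≈5.8× in the region statistic — the tests assert the
analytically correct value, not the design multiplier. No replicate
correlation QC, peak calling, or per-bin variance modeling is
implemented; the analysis reports plain ratios, as intended.
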