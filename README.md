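# spikechip

Quantitative ChIP-seq analysis of centromeric histone dynamics in
fission yeast, built for the study design in which an ATP-dependent
chromatin remodeler (the Ino80 complex) evicts histone H3 from
centromeres so the centromeric histone variant CENP-A can be deposited.
The package implements the full analysis chain — spike-in (ChIP-Rx)
calibration, SES background scaling, normalized fold-change tracks,
centromeric region enrichment, metagene profiling with k-means
high/low classification and hypergeometric gene-set overlap, and the
minichromosome loss-rate estimator — together with a dual-genome read
simulator so every stage runs and is tested without any deposited
sequencing data.

## The statistics at the core

With read totals split by the genome each read maps to (experimental vs
spike-in), the spike-in normalized IP/input ratio is

```
E^IP = (IP_exp / input_exp) / (IP_spike / input_spike)
```

and the scaling factor `N` satisfies `N · IP/input = E^IP` within a
sample or `N · IP_mut/IP_wt = E^IP_mut / E^IP_wt` between conditions —
the quantity that makes genome-wide histone changes visible across
samples. Samples without spike-in are scaled by signal extraction
scaling (SES): the background is the bin set maximizing the gap between
cumulative input and IP signal curves, and the input track is rescaled
so the background ratio is one. The minichromosome loss rate per
division is `100 · (1 − (F/I)^(1/N))` for initial/final retention
percentages `I`, `F` over `N` divisions. Gene-level analysis profiles
every gene from −0.5 kb of the TSS to +0.5 kb of the TES (bodies
rescaled to 100 columns), classifies genes into high/low enrichment by
exact 1-D 2-means, and scores the overlap of two high sets with the
upper-tail hypergeometric distribution. See `docs/methods.md` for
derivations, conventions and limitations.

## Worked example

The numbered drivers under `analysis/` run the whole simulated study;
each writes tables under `results/` and prints what it found:

```
$ python analysis/01_simulate_chip.py
h3_wt: 978,907 IP reads on the experimental genome, 21,093 on the spike-in genome
h3_ies6D: 980,927 IP reads on the experimental genome, 19,073 on the spike-in genome
...
$ python analysis/02_spike_normalization.py
h3_wt: E^IP = 1.4023, N = 1.3905
h3_ies6D: E^IP = 1.5431, N = 1.5272
mutant vs wt: calibrated IP fold change 1.1004 (scaling factor N = 1.0981) ...
$ python analysis/04_gene_profiles.py
44 genes with high Ies6 binding, 44 with high H3 increase in the mutant;
overlap 44 of 132 genes (hypergeometric p = 4.41e-36)
high-Ies6 set recovers 44/44 of the genes the simulation designated remodeler-bound
$ python analysis/05_loss_rates.py
wt: loss rate 0.180% ± 0.014 per division (3 colonies; simulated truth 0.2%)
ies6D: loss rate 2.034% ± 0.036 per division (3 colonies; simulated truth 2.0%)
```

Read together: the simulated `ies6Δ`-like mutant carries ~10 % more
total H3 IP signal than wild type once spike-calibrated (a change raw
ratios cannot see), the H3 increase is confined to the genes the
simulation marked remodeler-bound (hence the perfect 44/44 overlap with
the high-Ies6 class), and the mutant loses its minichromosome an order
of magnitude faster than wild type, recovering the simulated truth
within scoring noise.

The same study runs as one command through the CLI:

```
spikechip run --config configs/demo.yaml
```

which writes every stage's outputs plus a `manifest.json` of content
checksums (identical config and seed ⇒ identical checksums).
Individual stages are exposed as `spikechip simulate | normalize |
tracks | metagene | overlap | lossrate`.

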