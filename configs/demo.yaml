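# Demo configuration for `spikechip run`: a complete simulated study at
# modest depth, finishing in well under a minute on one CPU.
seed: 7
out_dir: results/demo
bin_width: 50
total_reads: 200000
mix_ratio: 0.125          # 1 spike-in cell per 8 experimental cells
h3_fold_change: 1.5       # mutant H3 effect on remodeler-bound bins
mutant: ies6D
pseudocount: 1.0
upstream: 500
downstream: 500
body_bins: 100
loss_p_wt: 0.002
loss_p_mut: 0.02
loss_divisions: 11
loss_initial_pct: 95.0
loss_colonies: 3
loss_cells: 2000
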