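"""End-to-end orchestration: simulate -> normalize -> tracks -> metagene
-> overlap -> loss rate, with plain files between stages and a manifest
of checksummed outputs.

Every stage is a thin composition of library calls; the pipeline exists
so a whole simulated study can be reproduced from one config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core, loss, normalization, occupancy, profiles, simulate

logger = logging.getLogger("spikechip")


@dataclass
class RunConfig:
    """Configuration of a full simulated-study run."""

    seed: int
    out_dir: Path
    bin_width: int = 50
    total_reads: int = 300_000
    mix_ratio: float = 1 / 8
    h3_fold_change: float = 1.5
    mutant: str = "ies6D"
    pseudocount: float = 1.0
    upstream: int = 500
    downstream: int = 500
    body_bins: int = 100
    loss_p_wt: float = 0.002
    loss_p_mut: float = 0.02
    loss_divisions: int = 11
    loss_initial_pct: float = 100.0
    loss_colonies: int = 3
    loss_cells: int = 2_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError(
                "a seed is required: the simulate stage is stochastic"
            )
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _mean_on_bins(track: core.BinnedTrack, bins: dict[str, np.ndarray]) -> float:
    vals = np.concatenate(
        [track.values[c][idx] for c, idx in bins.items() if idx.size]
    )
    return float(vals.mean())


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; return the manifest (also written to
    ``manifest.json``) mapping each output file to its sha256."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    stage_seeds = rng.integers(0, 2**31 - 1, size=8)

    logger.info("stage=layout bin_width=%d", cfg.bin_width)
    design = simulate.build_study_model(
        bin_width=cfg.bin_width, h3_fold_change=cfg.h3_fold_change,
        mutant_condition=cfg.mutant,
    )
    layout = design.model.layout
    core.write_domains_bed(layout.domains, out / "domains.bed")
    core.write_genes_bed(layout.genes, out / "genes.bed")

    # --- simulate: H3 ChIP with spike-in, wt and mutant -----------------
    def chip(condition, target, seed):
        cfg_sim = simulate.SimulationConfig(
            seed=int(seed),
            total_ip_reads=cfg.total_reads,
            total_input_reads=cfg.total_reads,
            mix_ratio=cfg.mix_ratio,
        )
        return simulate.simulate_chip(design.model, cfg_sim, condition, target)

    logger.info(
        "stage=simulate reads=%d mix_ratio=%.4f fold=%.2f",
        cfg.total_reads, cfg.mix_ratio, cfg.h3_fold_change,
    )
    h3_wt = chip("wt", "H3", stage_seeds[0])
    h3_mut = chip(cfg.mutant, "H3", stage_seeds[1])
    cenpa = chip("wt", "CENP-A", stage_seeds[2])
    ies6 = chip("wt", "Ies6", stage_seeds[3])
    for name, res in [
        ("h3_wt", h3_wt), (f"h3_{cfg.mutant}", h3_mut),
        ("cenpa_wt", cenpa), ("ies6_wt", ies6),
    ]:
        core.write_track(res.ip_exp, out / f"{name}_ip.bedgraph")
        core.write_track(res.input_exp, out / f"{name}_input.bedgraph")
    core.write_spikein_counts_tsv(
        {"h3_wt": h3_wt.counts, f"h3_{cfg.mutant}": h3_mut.counts},
        out / "spikein_counts.tsv",
    )

    # --- normalize ------------------------------------------------------
    res_wt = normalization.n_factor_ip_vs_input(h3_wt.counts)
    res_mut = normalization.n_factor_ip_vs_input(h3_mut.counts)
    res_mvw = normalization.n_factor_mut_vs_wt(h3_mut.counts, h3_wt.counts)
    ses_cenpa = normalization.ses_scale(cenpa.ip_exp, cenpa.input_exp)
    ses_ies6 = normalization.ses_scale(ies6.ip_exp, ies6.input_exp)
    pd.DataFrame(
        [
            {"contrast": "h3_wt_ip_vs_input", "e_ip": res_wt.e_ip,
             "n_factor": res_wt.n_factor, "mode": res_wt.mode},
            {"contrast": f"h3_{cfg.mutant}_ip_vs_input", "e_ip": res_mut.e_ip,
             "n_factor": res_mut.n_factor, "mode": res_mut.mode},
            {"contrast": f"h3_{cfg.mutant}_vs_wt", "e_ip": res_mvw.e_ip,
             "n_factor": res_mvw.n_factor, "mode": res_mvw.mode},
            {"contrast": "cenpa_ses", "e_ip": float("nan"),
             "n_factor": ses_cenpa, "mode": "ses"},
            {"contrast": "ies6_ses", "e_ip": float("nan"),
             "n_factor": ses_ies6, "mode": "ses"},
        ]
    ).to_csv(out / "normalization.tsv", sep="\t", index=False)
    logger.info(
        "stage=normalize e_ip_wt=%.4f e_ip_mut=%.4f n_mut_vs_wt=%.4f",
        res_wt.e_ip, res_mut.e_ip, res_mvw.n_factor,
    )

    # --- tracks ---------------------------------------------------------
    h3_change = occupancy.mutant_vs_wt_track(
        h3_mut.ip_exp, h3_wt.ip_exp, n_factor=res_mvw.n_factor,
        pseudocount=cfg.pseudocount,
    )
    core.write_track(h3_change, out / f"h3_{cfg.mutant}_vs_wt.bedgraph")
    # CENP-A fold enrichment of the central core over a euchromatic control
    cnt0 = layout.domains_labelled("cnt")[0]
    ctrl_gene = layout.genes[1]  # an unbound euchromatic gene
    target_iv = occupancy.Interval(cnt0.chrom, cnt0.start, cnt0.end)
    control_iv = occupancy.Interval(
        ctrl_gene.chrom, ctrl_gene.tss, ctrl_gene.tes
    )
    enrich = occupancy.region_fold_enrichment(
        cenpa.ip_exp, cenpa.input_exp, target_iv, control_iv
    )
    pd.DataFrame(
        [{
            "target": f"{target_iv.chrom}:{target_iv.start}-{target_iv.end}(cnt)",
            "control": f"{control_iv.chrom}:{control_iv.start}-{control_iv.end}",
            "fold_enrichment": enrich.fold_enrichment,
        }]
    ).to_csv(out / "region_enrichment.tsv", sep="\t", index=False)
    fold_bound = _mean_on_bins(h3_change, design.bound_bins)
    fold_unbound = _mean_on_bins(h3_change, design.unbound_bins)
    logger.info(
        "stage=tracks bound_fold=%.3f unbound_fold=%.3f cnt_enrichment=%.2f",
        fold_bound, fold_unbound, enrich.fold_enrichment,
    )

    # --- metagene + overlap --------------------------------------------
    ies6_ratio = occupancy.ratio_track(
        ies6.ip_exp, ies6.input_exp,
        n_factor=1.0 / ses_ies6, pseudocount=cfg.pseudocount,
    )
    m_ies6 = profiles.metagene_matrix(
        ies6_ratio, layout, cfg.upstream, cfg.downstream, cfg.body_bins
    )
    m_h3 = profiles.metagene_matrix(
        h3_change, layout, cfg.upstream, cfg.downstream, cfg.body_bins
    )
    m_ies6.to_frame().to_csv(out / "metagene_ies6.tsv", sep="\t")
    np.savetxt(
        out / "profile_ies6.tsv", profiles.average_profile(m_ies6),
        delimiter="\t",
    )
    order = profiles.heatmap_order(m_ies6)
    pd.Series(order, name="gene_id").to_csv(
        out / "heatmap_order_ies6.tsv", sep="\t", index=False
    )
    high_ies6, _ = profiles.kmeans_high_low(m_ies6.summary)
    high_h3, _ = profiles.kmeans_high_low(m_h3.summary)
    overlap = profiles.hypergeom_overlap(
        set(m_ies6.gene_ids), high_ies6, high_h3
    )
    pd.DataFrame(
        [{
            "universe": overlap.universe_size,
            "high_ies6": overlap.set_a_size,
            "high_h3_increase": overlap.set_b_size,
            "overlap": overlap.overlap,
            "p_value": overlap.p_value,
        }]
    ).to_csv(out / "overlap.tsv", sep="\t", index=False)
    logger.info(
        "stage=overlap |A|=%d |B|=%d k=%d p=%.3g",
        overlap.set_a_size, overlap.set_b_size, overlap.overlap,
        overlap.p_value,
    )

    # --- loss assay -----------------------------------------------------
    rows = []
    for strain, p in (("wt", cfg.loss_p_wt), (cfg.mutant, cfg.loss_p_mut)):
        obs = simulate.simulate_loss_assay(
            p_loss=p, n_divisions=cfg.loss_divisions,
            initial_pct=cfg.loss_initial_pct, colonies=cfg.loss_colonies,
            n_cells=cfg.loss_cells,
            seed=int(stage_seeds[4] + (0 if strain == "wt" else 1)),
        )
        core.write_loss_assay_tsv(obs, out / f"loss_assay_{strain}.tsv")
        result = loss.aggregate_loss(obs)
        rows.append(
            {"strain": strain, "mean_rate_pct": result.mean_rate,
             "sd_rate_pct": result.sd_rate, "n_colonies": result.n_colonies}
        )
        logger.info(
            "stage=lossrate strain=%s rate=%.3f%%±%.3f",
            strain, result.mean_rate, result.sd_rate,
        )
    pd.DataFrame(rows).to_csv(out / "loss_rates.tsv", sep="\t", index=False)

    # --- manifest -------------------------------------------------------
    files = sorted(
        p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(cfg).items()
        },
        "summary": {
            "e_ip_wt": res_wt.e_ip,
            "e_ip_mut": res_mut.e_ip,
            "n_mut_vs_wt": res_mvw.n_factor,
            "bound_fold_change": fold_bound,
            "unbound_fold_change": fold_unbound,
            "cnt_fold_enrichment": enrich.fold_enrichment,
            "overlap_p_value": overlap.p_value,
            "loss_rates": rows,
        },
        "files": {p.name: _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
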