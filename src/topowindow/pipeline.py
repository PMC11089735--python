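"""End-to-end orchestration over a synthetic genome.

``run_synthetic_pipeline`` chains every stage the package provides —
simulation, per-window tree inference loop-closure (optional), topology
classification, run detection, the D-statistic, the block permutation test,
region calling and gene overlap, and the exhaustive coalescent species
tree — writing tab-separated outputs plus a provenance manifest so a rerun
with the same config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import introgression, runscan, speciestree, synthetic, topology
from .config import (
    PipelineConfig,
    SYNTHETIC_ROLES,
    alias_bindings,
    synthetic_taxa,
)
from .treeio import TaxonSet

__all__ = ["run_synthetic_pipeline"]

log = logging.getLogger("topowindow")


def _catalogue(taxa: TaxonSet, roles: dict) -> topology.TopologyCatalogue:
    return topology.TopologyCatalogue.build(
        taxa,
        constraints=[roles["donor_pair"]],
        aliases=alias_bindings(roles),
    )


def run_synthetic_pipeline(
    sim_cfg: synthetic.SimulationConfig,
    pipe_cfg: PipelineConfig,
    outdir: str | Path,
    seed: int,
) -> dict:
    """Simulate a genome and run the full discordance/introgression analysis.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    roles = SYNTHETIC_ROLES
    taxa = synthetic_taxa()
    manifest: dict = {"seed": seed, "stages": {}}

    log.info("stage=simulate seed=%d", seed)
    dataset = synthetic.layout_genome(sim_cfg, rng)
    dataset.write(outdir / "simulated")
    manifest["stages"]["simulate"] = {"windows": len(dataset)}

    log.info("stage=classify windows=%d", len(dataset))
    catalogue = _catalogue(taxa, roles)
    window_trees = dataset.window_trees()
    classes = [catalogue.classify(wt.tree) for wt in window_trees]
    keys = [c.alias or c.canonical for c in classes]
    classified = dataset.windows.assign(class_key=keys)
    classified.to_csv(outdir / "classified.tsv", sep="\t", index=False)
    freq = topology.tabulate(classes, label=f"{sim_cfg.window_size}bp")
    pd.DataFrame(
        freq.to_rows(), columns=["class_key", "count", "frequency"]
    ).to_csv(outdir / "topology_frequencies.tsv", sep="\t", index=False)
    manifest["stages"]["classify"] = {
        "windows": len(classes), "classes": len(freq.counts),
    }

    log.info("stage=runscan")
    runs = runscan.detect_runs(classified)
    pd.DataFrame(runs).to_csv(outdir / "runs.tsv", sep="\t", index=False)
    summary = runscan.summarize_runs(runs, k_high=pipe_cfg.k_high)
    summary.to_csv(outdir / "run_summary.tsv", sep="\t", index=False)
    bins = runscan.bin_counts(classified, bin_size=pipe_cfg.bin_size)
    bins.to_csv(outdir / "bin_counts.tsv", sep="\t", index=False)
    manifest["stages"]["runscan"] = {"runs": len(runs)}
    assert sum(r.length for r in runs) == len(classes)

    log.info("stage=dstat")
    alignments = dataset.alignments(rng)
    quartet = (
        roles["cherry_pair"][0], roles["recipient"],
        roles["donor_pair"][0], roles["outgroup"],
    )
    block_bp = max(
        sim_cfg.window_size,
        sim_cfg.windows_per_chromosome * sim_cfg.window_size // 20,
    )
    patterns = synthetic.emit_site_patterns(alignments, quartet, block=block_bp)
    dres = introgression.d_statistic(patterns)
    pd.DataFrame([{
        "P1": quartet[0], "P2": quartet[1], "P3": quartet[2],
        "outgroup": quartet[3], "D": dres.D, "SE": dres.SE, "Z": dres.Z,
        "n_blocks": dres.n_blocks,
    }]).to_csv(outdir / "dstat.tsv", sep="\t", index=False)
    manifest["stages"]["dstat"] = {"D": dres.D, "Z": dres.Z}

    log.info("stage=introgression")
    track = introgression.distance_track(
        window_trees, [roles["recipient"]], list(roles["donor_pair"]),
        kind="patristic",
    )
    calls = introgression.call_regions(
        track, runs,
        intro_class="t2", resist_class="t1",
        intro_pct=pipe_cfg.intro_pct, intro_minrun=pipe_cfg.intro_minrun,
        resist_pct=pipe_cfg.resist_pct, resist_minrun=pipe_cfg.resist_minrun,
    )
    with open(outdir / "regions.bed", "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.kind}\t{c.run_length}\t+\n"
            )
    gene_hits = introgression.overlap_genes(calls, dataset.genes)
    gene_hits.to_csv(outdir / "region_genes.tsv", sep="\t", index=False)
    manifest["stages"]["regions"] = {
        "calls": len(calls), "genes": int(gene_hits["gene"].nunique()),
    }

    # permutation test on the longest introgression-topology run, against
    # the species-topology background, when both are large enough
    t1_idx = [i for i, k in enumerate(keys) if k == "t1"]
    t2_runs = sorted(
        (r for r in runs if r.class_key == "t2"), key=lambda r: -r.length
    )
    mrca_track = introgression.distance_track(
        window_trees, [roles["recipient"]], list(roles["cherry_pair"]),
        kind="mrca",
    )
    if t2_runs and len(t1_idx) >= pipe_cfg.perm_block:
        top = t2_runs[0]
        obs = mrca_track[top.start_ordinal : top.start_ordinal + top.length]
        p, _ = introgression.permutation_test(
            obs, mrca_track[t1_idx],
            block=min(pipe_cfg.perm_block, top.length),
            n_perm=pipe_cfg.n_perm, rng=rng, alternative="greater",
        )
        manifest["stages"]["permutation"] = {
            "run_length": top.length, "p": p,
        }

    log.info("stage=speciestree")
    best, table = speciestree.exhaustive_species_tree(
        [wt.tree for wt in window_trees], taxa,
        constraints=[roles["donor_pair"]],
    )
    table.to_csv(outdir / "species_tree_scores.tsv", sep="\t", index=False)
    manifest["stages"]["speciestree"] = {
        "best": best.alias or best.canonical,
    }

    manifest["config"] = {
        "pipeline": asdict(pipe_cfg),
        "simulation": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(sim_cfg).items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
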