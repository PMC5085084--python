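"""End-to-end pipeline orchestration.

Runs the full MSAP + deep-amplicon-sequencing workflow on a synthetic
two-pair study: simulate genomes/methylomes -> predicted MSAP spectra ->
binary band matrix -> Dice similarity + UPGMA dendrogram -> polymorphism
accounting -> primer-combination selection -> capacity report -> pooled
read simulation -> demultiplex -> quality filter -> contig clustering ->
directional differential sets -> consensual (repeatedly polymorphic)
contigs.  Every intermediate artifact is written to the run directory,
and a deterministic summary report collects the headline counts.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import contigs as ctg
from . import io as mio
from .config import PipelineConfig
from .contigs import AlignScoring
from .design import (
    average_amplicons_per_combination,
    capacity_estimate,
    select_primer_combinations,
)
from .digest import DEFAULT_COMBOS, revcomp
from .landscape import (
    build_band_matrix,
    polymorphic_percent,
    polymorphism_accounting,
    round_half_up,
    similarity_matrix,
    upgma_tree,
)
from .simulate import SyntheticExperiment, simulate_experiment, simulate_reads

__all__ = ["run_pipeline"]

logger = logging.getLogger("msapseq")


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def _canonical(seq: str) -> str:
    return min(seq, revcomp(seq))


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    *,
    experiment: Optional[SyntheticExperiment] = None,
) -> dict:
    """Execute every pipeline stage and write the run directory.

    When `experiment` is None a synthetic study is simulated from the
    config (the usual entry point); a pre-built experiment may be
    injected for testing.  Returns the summary report dict (also
    written as ``summary.json``).  Deterministic given config.seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    config.to_yaml(outdir / "config.yaml")
    logger.info("stage simulate: seed=%d", config.seed)

    sim_cfg = config.simulation()
    if experiment is None:
        experiment = simulate_experiment(sim_cfg)
    exp = experiment

    mio.write_fasta(
        {b.id: b.sequence for b in exp.genomes.values()}, outdir / "genomes.fasta"
    )
    mio.write_methylome(
        {
            **{f"{b.id}" : b.methylome for b in exp.genomes.values()},
            **{
                f"{exp.genomes[p].id}_somaclone": m
                for p, m in exp.somaclone_methylomes.items()
            },
        },
        outdir / "methylomes.tsv",
    )
    truth_rows = [
        {
            "pair_id": t.pair_id,
            "position": t.position,
            "old_state": t.old_state.value,
            "new_state": t.new_state.value,
            "shared": t.shared,
            "shared_id": t.shared_id or "",
            "expected_amplicons": ";".join(
                f"{c}:{ch}:{s}:{d}" for c, ch, s, d in t.expected_amplicons
            ),
        }
        for t in exp.truth
    ]
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)

    logger.info("stage spectra: %d primer combinations", len(exp.combos))
    spectra = exp.sample_spectra()
    mio.write_spectra(spectra, outdir / "spectra.csv")

    logger.info("stage matrix")
    matrix = build_band_matrix(spectra, bin_width=config.bin_width)
    mio.write_band_matrix(matrix, outdir / "band_matrix.tsv")

    logger.info("stage similarity + tree")
    sim = similarity_matrix(matrix)
    sim.to_csv(outdir / "similarity.csv")
    tree = upgma_tree(1.0 - sim)
    (outdir / "upgma.nwk").write_text(tree.newick + "\n")

    def _mean_s(pairs: list[tuple[str, str]]) -> float:
        return float(np.mean([sim.loc[a, b] for a, b in pairs]))

    samples = matrix.samples
    within, between = [], []
    for pid in sorted(exp.genomes):
        for role in ("standard", "somaclone"):
            reps = [s for s in samples if s.startswith(f"P{pid}_{role}_")]
            within.extend(
                (reps[i], reps[j])
                for i in range(len(reps))
                for j in range(i + 1, len(reps))
            )
        std = [s for s in samples if s.startswith(f"P{pid}_standard_")]
        som = [s for s in samples if s.startswith(f"P{pid}_somaclone_")]
        between.extend((a, b) for a in std for b in som)
    s_within = _mean_s(within) if within else float("nan")
    s_between = _mean_s(between)

    logger.info("stage accounting + combination selection")
    groups = {
        s: (s.split("_")[0], "standard" if "_standard_" in s else "somaclone")
        for s in samples
    }
    account = polymorphism_accounting(matrix, groups)
    account.table.to_csv(outdir / "polymorphism_account.tsv", sep="\t")
    selected = select_primer_combinations(account, config.max_combos)
    combo_by_id = {c.id: c for c in exp.combos}
    selected_combos = [combo_by_id[c] for c in selected]

    plan = capacity_estimate(
        config.mean_amplicon_length,
        config.amplicons_per_combination,
        config.n_pooled_samples,
        config.target_coverage,
        len(selected),
        device_capacity=config.device_capacity,
    )
    (outdir / "capacity.json").write_text(json.dumps(plan.report(), indent=2, sort_keys=True) + "\n")

    logger.info("stage reads: coverage=%dx error=%g", sim_cfg.coverage, sim_cfg.read_error_rate)
    pools_amp = exp.amplicon_pools(selected_combos)
    rng = np.random.default_rng(sim_cfg.seed)
    reads = simulate_reads(pools_amp, sim_cfg, mid_table=config.mid_table, rng=rng)
    mio.write_fastq(reads, outdir / "reads.fastq")

    logger.info("stage demultiplex")
    pools, unassigned = ctg.demultiplex(reads, config.mid_table, config.demux_max_mismatch)

    logger.info("stage trim/filter")
    filtered: dict[str, list] = {}
    n_filtered_out = 0
    for pool_no, rs in pools.items():
        kept = []
        for r in rs:
            if config.adaptors:
                r = ctg.trim_adaptors(
                    r,
                    config.adaptors,
                    min_length=config.trim_min_length,
                    min_mean_quality=config.trim_min_quality,
                )
            elif len(r.bases) < config.trim_min_length or r.mean_quality() < config.trim_min_quality:
                r = None
            if r is not None:
                kept.append(r)
            else:
                n_filtered_out += 1
        filtered[pool_no] = kept

    logger.info("stage cluster")
    contigs = {
        pool_no: ctg.cluster_contigs(
            rs, config.min_identity, config.min_reads, pool=pool_no
        )
        for pool_no, rs in sorted(filtered.items())
    }
    for pool_no, cs in contigs.items():
        mio.write_contigs_fasta(cs, outdir / f"contigs_pool{pool_no}.fasta")

    logger.info("stage differential + consensual")
    scoring = AlignScoring()
    d = {
        "pair1_standard_only": ctg.differential_set(contigs["1"], contigs["2"], config.e_threshold, scoring),
        "pair1_somaclone_only": ctg.differential_set(contigs["2"], contigs["1"], config.e_threshold, scoring),
        "pair2_standard_only": ctg.differential_set(contigs["3"], contigs["4"], config.e_threshold, scoring),
        "pair2_somaclone_only": ctg.differential_set(contigs["4"], contigs["3"], config.e_threshold, scoring),
    }
    consensual = ctg.repeated_polymorphic(
        {"loss": d["pair1_standard_only"], "gain": d["pair1_somaclone_only"]},
        {"loss": d["pair2_standard_only"], "gain": d["pair2_somaclone_only"]},
        config.e_threshold,
        scoring,
    )
    report_rows = []
    for name, cs in d.items():
        for c in cs:
            report_rows.append(
                {"contig": c.id, "set": name, "reads": c.read_count, "length": len(c.consensus)}
            )
    pd.DataFrame(report_rows, columns=["contig", "set", "reads", "length"]).to_csv(
        outdir / "differential.tsv", sep="\t", index=False
    )
    mio.write_contigs_fasta([c for c, _h, _d1, _d2 in consensual], outdir / "consensual.fasta")
    cons_rows = [
        {
            "contig": c.id,
            "direction": d1,
            "partner": h.subject_id,
            "partner_direction": d2,
            "e_value": f"{h.e_value:.3e}",
        }
        for c, h, d1, d2 in consensual
    ]
    pd.DataFrame(
        cons_rows, columns=["contig", "direction", "partner", "partner_direction", "e_value"]
    ).to_csv(outdir / "consensual.tsv", sep="\t", index=False)

    truth_shared = {_canonical(s) for s in exp.expected_shared_sequences()}
    found = {_canonical(c.consensus) for c, _h, _d1, _d2 in consensual}
    total_bands = int(matrix.data.to_numpy().any(axis=0).sum())
    summary = {
        "seed": config.seed,
        "n_samples": len(samples),
        "n_bands": total_bands,
        "avg_amplicons_per_combination": average_amplicons_per_combination(
            total_bands, len(exp.combos)
        ),
        "mean_similarity_within_variant": round_half_up(s_within, 4),
        "mean_similarity_between_variant": round_half_up(s_between, 4),
        "percent_polymorphic_within": round_half_up(polymorphic_percent(s_within), 2),
        "percent_polymorphic_between": round_half_up(polymorphic_percent(s_between), 2),
        "polymorphic_within_both_pairs": account.total_within_both(),
        "selected_combinations": selected,
        "capacity_total_nt": plan.total_nt,
        "n_reads": len(reads),
        "n_unassigned": len(unassigned),
        "n_filtered_out": n_filtered_out,
        "reads_per_pool": {k: len(v) for k, v in sorted(pools.items())},
        "contigs_per_pool": {k: len(v) for k, v in sorted(contigs.items())},
        "differential_counts": {k: len(v) for k, v in d.items()},
        "n_consensual": len(consensual),
        "n_truth_shared": len(truth_shared),
        "consensual_matches_truth": sorted(found) == sorted(truth_shared),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info(
        "done: %d consensual contigs (truth shared %d, match=%s)",
        summary["n_consensual"],
        summary["n_truth_shared"],
        summary["consensual_matches_truth"],
    )
    return summary
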