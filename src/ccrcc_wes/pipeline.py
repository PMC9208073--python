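"""End-to-end orchestration over a cohort directory.

Consumes the file layout written by :func:`ccrcc_wes.synthetic.emit_cohort`
(or any directory with the same per-sample tables) and runs
purity -> SNV filtering -> SCNA calling -> phylogenies -> cohort
statistics, writing deterministic TSV/SEG/Newick outputs.  All
randomness (CBS permutations, purity bootstrap) is seeded from the run
configuration, so a rerun with the same inputs and seed is
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import phylo as phylo_mod
from . import scna, snv
from .io_formats import (
    RunConfig,
    annotate_cosmic,
    read_cosmic_table,
    read_coverage_table,
    read_cytoband_bed,
    read_het_snp_table,
    read_sample_metadata,
    read_variant_table,
    write_newick,
    write_seg,
    write_variant_table,
)
from .purity import estimate_sample_purity, write_purity_table

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


def run_cohort(in_dir: str | Path, out_dir: str | Path,
               config: RunConfig | None = None) -> dict:
    """Run the full analysis over a cohort directory.

    Returns a summary dict with per-sample purity estimates, TMB and
    burden tables, per-patient tree metrics and the cohort tables.
    """
    in_dir = Path(in_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    meta = read_sample_metadata(in_dir / "meta.tsv")
    cytobands = read_cytoband_bed(in_dir / "cytobands.bed")
    cosmic_path = in_dir / "cosmic_counts.tsv"
    cosmic = read_cosmic_table(cosmic_path) if cosmic_path.exists() else {}
    sample_ids = sorted(m.sample_id for m in meta)
    streams = np.random.SeedSequence(config.rng_seed).spawn(
        max(len(sample_ids), 1))

    purity_by_sample: dict[str, float] = {}
    purity_estimates = {}
    segments_by_sample: dict[str, list] = {}
    calls_by_sample: dict[str, list] = {}
    tmb_rows = []
    burden_rows = []
    for i, sid in enumerate(sample_ids):
        rng = np.random.default_rng(streams[i])
        coverage = read_coverage_table(in_dir / f"{sid}.coverage.tsv")
        snps = read_het_snp_table(in_dir / f"{sid}.hetsnps.tsv")
        calls = read_variant_table(in_dir / f"{sid}.variants.tsv")
        annotate_cosmic(calls, cosmic)

        est = estimate_sample_purity(coverage, snps, config, rng=rng)
        purity_estimates[sid] = est
        purity_by_sample[sid] = est.purity

        segments = scna.call_sample(coverage, est.purity, cytobands,
                                    config, rng=rng)
        segments_by_sample[sid] = segments
        write_seg(segments, out_dir / f"{sid}.seg", sid)

        snv.filter_variants(calls, est.purity, segments, config)
        calls_by_sample[sid] = calls
        write_variant_table(calls, out_dir / f"{sid}.filtered.tsv")

        tmb = snv.compute_tmb(calls, coverage, config)
        tmb_rows.append({"sample_id": sid,
                         "n_nonsynonymous": tmb.n_nonsynonymous,
                         "covered_mb": tmb.covered_mb,
                         "tmb": tmb.tmb,
                         "indel_fraction": tmb.indel_fraction})
        burden = scna.cna_burden(segments,
                                 include_sex=config.include_sex_chromosomes)
        burden_rows.append({
            "sample_id": sid,
            "altered_bp": burden.altered_bp,
            "total_bp": burden.total_bp,
            "fraction_altered": burden.fraction_altered,
            "review_flag": scna.needs_ploidy_review(
                segments, include_sex=config.include_sex_chromosomes)})
        log.info("sample %s: purity %.3f, %d segments, %d kept variants",
                 sid, est.purity, len(segments),
                 sum(1 for c in calls if c.kept))

    write_purity_table(purity_estimates, out_dir / "purity.tsv")
    tmb_df = pd.DataFrame(tmb_rows)
    burden_df = pd.DataFrame(burden_rows)
    if not tmb_df.empty:
        tmb_df.to_csv(out_dir / "tmb.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)
        burden_df.to_csv(out_dir / "burden.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)

    # per-patient phylogenies (patients with >= 2 samples)
    by_patient: dict[str, list[str]] = {}
    for m in meta:
        by_patient.setdefault(m.patient_id, []).append(m.sample_id)
    tree_rows = []
    trees = {}
    for pid in sorted(by_patient):
        sids = sorted(by_patient[pid])
        if len(sids) < 2:
            continue
        matrix = phylo_mod.build_presence_matrix(
            {s: calls_by_sample[s] for s in sids},
            purity_by_sample, segments_by_sample,
            threshold=config.clonality_presence_threshold)
        if matrix.presence.empty:
            log.warning("patient %s: no SNVs usable for phylogeny", pid)
            continue
        result = phylo_mod.build_tree(matrix)
        trees[pid] = result
        write_newick(result.tree, out_dir / f"{pid}.tree.nwk")
        _write_edge_table(result, matrix,
                          out_dir / f"{pid}.edges.tsv")
        metrics = phylo_mod.tree_metrics(result.tree)
        tree_rows.append({"patient_id": pid, **metrics,
                          "n_discarded_patterns":
                              len(result.discarded_patterns)})
    if tree_rows:
        pd.DataFrame(tree_rows).to_csv(out_dir / "tree_metrics.tsv",
                                       sep="\t", index=False,
                                       float_format=_FLOAT_FMT)

    # cohort tables
    summary: dict = {
        "purity": purity_estimates,
        "tmb": tmb_df,
        "burden": burden_df,
        "trees": trees,
        "tree_metrics": pd.DataFrame(tree_rows),
        "segments": segments_by_sample,
        "calls": calls_by_sample,
    }
    if meta:
        freq = cohort_mod.gene_frequencies(calls_by_sample, meta)
        freq.to_csv(out_dir / "gene_frequencies.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT)
        comparisons = cohort_mod.compare_by_treatment(
            calls_by_sample,
            {r["sample_id"]: r["tmb"] for r in tmb_rows},
            {r["sample_id"]: r["indel_fraction"] for r in tmb_rows},
            {r["sample_id"]: r["fraction_altered"] for r in burden_rows},
            meta)
        comparisons.to_csv(out_dir / "comparisons.tsv", sep="\t",
                           index=False, float_format=_FLOAT_FMT)
        patient_segments = {
            pid: [segments_by_sample[s] for s in sorted(sids)]
            for pid, sids in by_patient.items()}
        recurrence = scna.cohort_recurrence(patient_segments, cytobands)
        recurrence.to_csv(out_dir / "recurrence.tsv", sep="\t", index=False)
        summary["gene_frequencies"] = freq
        summary["comparisons"] = comparisons
        summary["recurrence"] = recurrence
    return summary


def _write_edge_table(result, matrix, path: Path) -> None:
    """TSV of SNV-to-edge assignments for one patient's tree."""
    rows = []

    def walk(node, parent_label):
        label = node.name or "+".join(sorted(_leafset(node)))
        for key in node.snvs:
            rows.append({"edge": f"{parent_label}->{label}",
                         "variant": key,
                         "gene": matrix.variant_genes.get(key, "")})
        for c in node.children:
            walk(c, label)

    def _leafset(node):
        if node.is_leaf:
            return {node.name}
        out = set()
        for c in node.children:
            out |= _leafset(c)
        return out

    for c in result.tree.root.children:
        walk(c, "germline")
    pd.DataFrame(rows, columns=["edge", "variant", "gene"]).to_csv(
        path, sep="\t", index=False)
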