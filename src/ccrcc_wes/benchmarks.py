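"""Seeded recovery benchmarks exercising every pipeline stage.

Each function regenerates its synthetic inputs from a seed, runs the
relevant part of the analysis and measures recovery against the
generating truth.  They are used both by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import logging
import tempfile
from pathlib import Path

import numpy as np
from scipy import stats as sp_stats

from . import phylo, scna, snv
from .cohort import mann_whitney_u
from .io_formats import CaptureRegion, RunConfig
from .pipeline import run_cohort
from .purity import estimate_sample_purity
from .scna import Log2Profile, classify_segments, segment_cbs
from .synthetic import (
    SimConfig,
    build_reference,
    emit_cohort,
    simulate_cohort,
    simulate_coverage,
    simulate_het_snps,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# purity recovery
# ---------------------------------------------------------------------------

def purity_recovery(seed: int,
                    purities: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5,
                                                   0.6, 0.7, 0.8, 0.9),
                    n_reps: int = 20, n_snps: int = 334,
                    depth: float = 100.0) -> dict:
    """Purity estimation error over a grid of true purities.

    Each replicate simulates one sample whose genome carries
    whole-chromosome hemizygous losses of chromosomes 3, 9 and 14 (a
    common ccRCC karyotype), overdispersed coverage at the given depth
    and ``n_snps`` het SNPs, then runs the full two-pass estimate
    (first-pass CBS at purity 1, candidate selection, folded-fraction
    inversion).
    """
    config = SimConfig()
    run_config = RunConfig()
    regions, _ = build_reference(config)
    chrom_len = config.chrom_length
    true_segments = [("3", 0, chrom_len, 1), ("9", 0, chrom_len, 1),
                     ("14", 0, chrom_len, 1)]
    root = np.random.SeedSequence(seed)
    streams = iter(root.spawn(len(purities) * n_reps))
    errors = []
    for p_true in purities:
        for _ in range(n_reps):
            rng = np.random.default_rng(next(streams))
            cov = simulate_coverage(regions, true_segments, p_true, depth,
                                    config.coverage_dispersion, rng)
            snps = simulate_het_snps(true_segments, p_true, n_snps, depth,
                                     rng, regions)
            est = estimate_sample_purity(cov, snps, run_config, rng=rng)
            errors.append(abs(est.purity - p_true))
    errors = np.asarray(errors)
    return {"mae": float(errors.mean()),
            "max_error": float(errors.max()),
            "n": int(errors.size)}


# ---------------------------------------------------------------------------
# segmentation recovery
# ---------------------------------------------------------------------------

def _profile_from_values(values: np.ndarray, chrom: str = "1",
                         region_len: int = 5000) -> Log2Profile:
    regions = [CaptureRegion(chrom, i * region_len * 2,
                             i * region_len * 2 + region_len)
               for i in range(len(values))]
    v = np.asarray(values, dtype=float)
    return Log2Profile(regions=regions, log2_raw=v, log2_corrected=v)


def segmentation_recovery(seed: int, n_regions: int = 200,
                          noise_sd: float = 0.2,
                          nperm: int = 1000) -> dict:
    """CBS recovery on planted profiles.

    Three instances: a constant profile (must return exactly one
    segment), a step of height -1 at the midpoint (breakpoint within
    +-3 regions, segment means within +-0.1, loss/deletion boundary
    classes correct) and a two-event profile (gain +0.6 and deletion
    -1.2) whose call classes must be recovered.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    config = RunConfig()

    flat = rng.normal(0.0, noise_sd, n_regions)
    segs_flat = segment_cbs(_profile_from_values(flat), nperm=nperm,
                            rng=rng)

    half = n_regions // 2
    truth = np.zeros(n_regions)
    truth[half:] = -1.0
    step = truth + rng.normal(0.0, noise_sd, n_regions)
    segs_step = segment_cbs(_profile_from_values(step), nperm=nperm,
                            rng=rng)
    classify_segments(segs_step, config)
    boundary_err = np.inf
    mean_err = np.inf
    calls_ok = False
    if len(segs_step) == 2:
        boundary_err = abs(segs_step[0].n_regions - half)
        mean_err = max(abs(segs_step[0].seg_mean - 0.0),
                       abs(segs_step[1].seg_mean + 1.0))
        # the planted -1 step sits exactly on the loss/deletion
        # boundary; either side of it is consistent with +-0.1 means
        calls_ok = (segs_step[0].call == "neutral"
                    and segs_step[1].call in ("loss", "deletion"))

    two = np.zeros(n_regions)
    two[50:80] = 0.6
    two[120:150] = -1.2
    two_obs = two + rng.normal(0.0, noise_sd, n_regions)
    segs_two = segment_cbs(_profile_from_values(two_obs), nperm=nperm,
                           rng=rng)
    classify_segments(segs_two, config)
    calls_two = [s.call for s in segs_two]
    two_ok = ("gain" in calls_two and "deletion" in calls_two
              and sum(1 for c in calls_two if c != "neutral") == 2)

    conservation = (sum(s.n_regions for s in segs_step) == n_regions
                    and sum(s.n_regions for s in segs_two) == n_regions)
    return {
        "constant_n_segments": len(segs_flat),
        "step_n_segments": len(segs_step),
        "breakpoint_error_regions": float(boundary_err),
        "seg_mean_error": float(mean_err),
        "step_calls_ok": bool(calls_ok),
        "two_event_calls_ok": bool(two_ok),
        "region_conservation_ok": bool(conservation),
    }


# ---------------------------------------------------------------------------
# tree recovery
# ---------------------------------------------------------------------------

def tree_recovery(seed: int, n_patients: int = 50) -> dict:
    """Phylogeny recovery over seeded multi-region patients.

    Patients carry 3-4 samples at purity 0.4-0.9 and default SNV rates;
    the pipeline (SCNA calls at true purity, somatic filters, presence
    matrix, perfect phylogeny) must reproduce the simulated topology
    and the planted truncal SNV count.
    """
    config = SimConfig(n_patients=n_patients,
                       n_multi_sample_patients=n_patients,
                       multi_sample_range=(3, 4),
                       purity_range=(0.4, 0.9),
                       rng_seed=seed)
    run_config = RunConfig()
    truth, obs = simulate_cohort(config)
    n_ok = 0
    truncal_rel = []
    conservation_ok = True
    for pid, tp in truth.patients.items():
        calls_by, segs_by, pur_by = {}, {}, {}
        for sid in tp.sample_ids:
            p = tp.purity[sid]
            segs = scna.call_sample(obs["tables"][sid]["coverage"], p,
                                    truth.cytobands, run_config, rng=2)
            calls = obs["tables"][sid]["variants"]
            snv.filter_variants(calls, p, segs, run_config)
            calls_by[sid] = calls
            segs_by[sid] = segs
            pur_by[sid] = p
        matrix = phylo.build_presence_matrix(
            calls_by, pur_by, segs_by,
            run_config.clonality_presence_threshold)
        result = phylo.build_tree(matrix)
        clades = result.tree.clades()
        n = len(tp.sample_ids)
        inferred = {c for c, length in clades.items()
                    if 1 < len(c) < n and length > 0}
        n_ok += inferred == tp.nontrivial_clades()
        planted = tp.truncal_snv_count()
        truncal = clades.get(frozenset(tp.sample_ids), 0.0)
        truncal_rel.append((truncal - planted) / max(planted, 1))
        if result.tree.total_length() != result.n_snvs_used:
            conservation_ok = False
    return {
        "recovery_rate": n_ok / n_patients,
        "truncal_rel_err_mean": float(np.mean(truncal_rel)),
        "truncal_rel_err_worst": float(np.max(np.abs(truncal_rel))),
        "edge_conservation_ok": bool(conservation_ok),
        "n": n_patients,
    }


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def null_type1_error(seed: int, n_sims: int = 2000, n_a: int = 30,
                     n_b: int = 38, alpha: float = 0.05) -> dict:
    """Empirical size of the two-sided Mann-Whitney test under the null
    (both groups standard normal, cohort-like group sizes)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rejections = 0
    for _ in range(n_sims):
        a = rng.normal(size=n_a)
        b = rng.normal(size=n_b)
        _, p = mann_whitney_u(a, b)
        rejections += p < alpha
    return {"type1_error": rejections / n_sims, "n": n_sims}


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def cohort_end_to_end(seed: int, n_patients: int = 44,
                      work_dir: str | Path | None = None) -> dict:
    """Simulate a full cohort, run the pipeline twice and summarize.

    Checks byte-identical reruns with a fixed seed, and reports the
    quantities a reader would compare against a real metastatic ccRCC
    cohort: top gene mutation frequencies, recurrent cytoband loss/gain
    patient counts, median TMB and indel fraction.
    """
    config = SimConfig(n_patients=n_patients, rng_seed=seed)
    run_config = RunConfig(rng_seed=seed)

    def run_once(base: Path, tag: str):
        cohort_dir = base / f"cohort_{tag}"
        out_dir = base / f"out_{tag}"
        truth = emit_cohort(config, cohort_dir)
        summary = run_cohort(cohort_dir, out_dir, run_config)
        return truth, summary, cohort_dir, out_dir

    def digest(d: Path) -> dict[str, bytes]:
        return {f.name: f.read_bytes() for f in sorted(d.iterdir())}

    if work_dir is None:
        ctx: tempfile.TemporaryDirectory | None = (
            tempfile.TemporaryDirectory())
        base = Path(ctx.name)
    else:
        ctx = None
        base = Path(work_dir)
        base.mkdir(parents=True, exist_ok=True)
    try:
        truth, summary, cdir1, odir1 = run_once(base, "a")
        _, _, cdir2, odir2 = run_once(base, "b")
        identical = (digest(cdir1) == digest(cdir2)
                     and digest(odir1) == digest(odir2))
        freq = summary["gene_frequencies"].set_index("gene")
        rec = summary["recurrence"].set_index("cytoband")
        tmb = summary["tmb"]
        n_loss_truth = {}
        for band in ("3p25", "9p21", "14q25", "13q14", "6p21"):
            n_loss_truth[band] = sum(
                1 for p in truth.patients.values()
                if any(e.cytoband == band for e in p.events))
        out = {
            "deterministic_rerun": bool(identical),
            "n_patients": n_patients,
            "n_samples": len(summary["purity"]),
            "gene_frequency_pct": {
                g: round(100 * freq.loc[g, "frequency"], 1)
                for g in ("SETD2", "PBRM1", "APC", "VHL")
                if g in freq.index},
            "loss_patients": {
                band: int(rec.loc[band, "loss_patients"])
                for band in ("3p25", "9p21", "14q25", "13q14")},
            "gain_patients_5q": int(rec.loc["5q", "gain_patients"]),
            "planted_loss_patients": n_loss_truth,
            "median_tmb": float(tmb["tmb"].median()),
            "median_indel_fraction":
                float(tmb["indel_fraction"].median()),
        }
        return out
    finally:
        if ctx is not None:
            ctx.cleanup()


def recurrence_recovery(seed: int, n_patients: int = 50,
                        band: str = "3p25", prevalence: float = 0.4) -> dict:
    """Planted-prevalence recovery for one recurrent loss cytoband.

    Plants the band's loss at the given patient-level prevalence, runs
    purity estimation and SCNA calling per sample and checks that the
    planted prevalence lies inside the binomial 95% CI of the recovered
    patient count.
    """
    menu = tuple((b, e, prevalence if b == band else p)
                 for b, e, p in SimConfig().driver_cnv_menu)
    config = SimConfig(n_patients=n_patients, driver_cnv_menu=menu,
                       vhl_pathway_truncal_prob=0.0, rng_seed=seed)
    run_config = RunConfig(rng_seed=seed)
    truth, obs = simulate_cohort(config)
    patient_segments = {}
    for pid, tp in truth.patients.items():
        per_sample = []
        for sid in tp.sample_ids:
            cov = obs["tables"][sid]["coverage"]
            snps = obs["tables"][sid]["hetsnps"]
            est = estimate_sample_purity(cov, snps, run_config, rng=3)
            per_sample.append(scna.call_sample(cov, est.purity,
                                               truth.cytobands,
                                               run_config, rng=3))
        patient_segments[pid] = per_sample
    rec = scna.cohort_recurrence(patient_segments, truth.cytobands)
    k = int(rec.set_index("cytoband").loc[band, "loss_patients"])
    lo, hi = sp_stats.binom.interval(0.95, n_patients, k / n_patients) \
        if k else (0, 0)
    ci_lo = lo / n_patients
    ci_hi = hi / n_patients
    planted = sum(1 for p in truth.patients.values()
                  if any(e.cytoband == band for e in p.events))
    return {
        "recovered_patients": k,
        "recovered_prevalence": k / n_patients,
        "planted_patients": planted,
        "planted_prevalence_target": prevalence,
        "ci_low": float(ci_lo),
        "ci_high": float(ci_hi),
        "within_ci": bool(ci_lo <= planted / n_patients <= ci_hi),
        "n": n_patients,
    }
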