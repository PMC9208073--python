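"""Tumor purity estimation from heterozygous-SNP allelic imbalance.

In an admixed specimen with tumor fraction p, a germline-het SNP lying
on a hemizygous (one-copy) loss has expected tumor alt fraction
1/(2-p) on the retained allele and (1-p)/(2-p) on the lost allele.
Folding the fraction to b = max(f, 1-f) removes the allele identity, so
under one-copy loss E[b] = 1/(2-p) and purity inverts as
p = 2 - 1/median(b).  Candidate one-copy-loss segments come from a
first-pass segmentation of the uncorrected log2 profile; the estimate
feeds back into VAF and log2 correction (two-pass design).

When no informative SNPs overlie a candidate loss, the sample falls
back to purity 1.0 with a loud warning and is analyzed uncorrected.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import CoverageRow, HetSNP, RunConfig, Segment
from .scna import compute_log2, segment_cbs

log = logging.getLogger(__name__)

PURITY_FLOOR = 0.05


@dataclass
class PurityEstimate:
    """Point estimate with a percentile-bootstrap interval."""

    purity: float
    n_informative_snps: int
    ci_low: float
    ci_high: float
    method_flag: str  # "informative" | "fallback_neutral"

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValueError("purity must lie in (0, 1]")


def select_informative_snps(snps: Iterable[HetSNP], min_depth: int = 20,
                            het_band: tuple[float, float] = (0.4, 0.6),
                            ) -> list[HetSNP]:
    """Keep SNPs heterozygous in the normal and well covered in both
    samples: normal alt fraction inside ``het_band`` and both depths
    >= ``min_depth``."""
    lo, hi = het_band
    return [s for s in snps
            if lo <= s.normal_alt_fraction <= hi
            and s.tumor_depth >= min_depth and s.normal_depth >= min_depth]


def candidate_loss_segments(segments: Iterable[Segment],
                            log2_low: float = -1.0,
                            log2_high: float = -0.02) -> list[Segment]:
    """Segments of the *raw* profile consistent with a one-copy loss.

    The band is deliberately wide at the top: at low purity a hemizygous
    loss barely depresses the raw ratio, so any segment below neutral is
    admitted and the allelic-imbalance test inside
    :func:`estimate_purity` rejects segments that are merely drifting
    noise.  The lower bound excludes homozygous deletions, where the
    allelic signal degenerates; the upper bound excludes gains, which
    also show folded imbalance but would invert incorrectly.
    """
    return [s for s in segments if log2_low <= s.seg_mean <= log2_high]


def _fold(fractions: np.ndarray) -> np.ndarray:
    return np.maximum(fractions, 1.0 - fractions)


# median of |Binomial(d, 1/2)/d - 1/2| is ~ 0.674 * 0.5 / sqrt(d): the
# folded fraction of a *neutral* het SNP sits above 0.5 by this much
_HALF_NORMAL_MEDIAN = 0.6745
_MEDIAN_SE_FACTOR = 1.2533  # SE(median) = 1.2533 * sigma / sqrt(n)


@dataclass
class _SegmentImbalance:
    """Folded-fraction summary of one candidate segment's SNPs."""

    snps: list
    median_b: float
    se: float
    z: float  # excess over the folded-noise null, in SE units


def _segment_imbalance(seg_snps: Sequence[HetSNP]) -> _SegmentImbalance:
    b = _fold(np.array([s.tumor_alt_fraction for s in seg_snps]))
    depths = np.array([s.tumor_depth for s in seg_snps], dtype=float)
    sd = 0.5 / np.sqrt(max(np.median(depths), 1.0))
    null_median = 0.5 + _HALF_NORMAL_MEDIAN * sd
    se = _MEDIAN_SE_FACTOR * sd / np.sqrt(len(b))
    med = float(np.median(b))
    return _SegmentImbalance(snps=list(seg_snps), median_b=med, se=se,
                             z=(med - null_median) / se)


def purity_from_folded(b: np.ndarray) -> float:
    """Invert the one-copy-loss relation E[b] = 1/(2-p) at the median,
    clamped to (0.05, 1]; folded fractions at exactly 0.5 (no imbalance)
    clamp to the lower bound."""
    med = min(float(np.median(b)), 1.0 - 1e-9)
    return float(np.clip(2.0 - 1.0 / med, PURITY_FLOOR, 1.0))


def estimate_purity(snps: Sequence[HetSNP],
                    loss_segments: Sequence[Segment],
                    rng: np.random.Generator | int | None = None,
                    n_bootstrap: int = 200,
                    min_snps: int = 10) -> PurityEstimate:
    """Invert folded allelic fractions over one-copy-loss segments.

    ``snps`` should already be informative (see
    :func:`select_informative_snps`).  Per candidate segment, the
    folded fractions b = max(f, 1-f) are screened against the null of
    folded binomial noise at the observed depths (a depressed log2 mean
    without allelic imbalance is coverage drift, not a loss).  The most
    significant segment anchors the estimate; other passing segments
    are pooled only when their median b agrees with the anchor, so a
    chromosome that merely drifted low cannot dilute a strong loss
    signal.  The estimate is p = 2 - 1/median(b) over the pooled SNPs,
    clamped to (0.05, 1], with a seeded percentile bootstrap interval.
    With no imbalanced segment or fewer than ``min_snps`` pooled SNPs
    the sample falls back to purity 1.0 (flag ``fallback_neutral``).
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    stats: list[_SegmentImbalance] = []
    for seg in loss_segments:
        seg_snps = [s for s in snps
                    if seg.overlaps(s.chrom, s.pos - 1, s.pos)]
        if seg_snps:
            stats.append(_segment_imbalance(seg_snps))
    passing = [c for c in stats if c.z >= 0.5]
    on_loss: list[HetSNP] = []
    if passing:
        anchor = max(passing, key=lambda c: c.z)
        for c in passing:
            tol = max(0.02, 3.0 * float(np.hypot(anchor.se, c.se)))
            if abs(c.median_b - anchor.median_b) <= tol:
                on_loss.extend(c.snps)
    if len(on_loss) < min_snps:
        log.warning(
            "purity fallback: %d informative SNPs on imbalanced candidate "
            "loss segments (need %d); analyzing sample uncorrected "
            "(purity=1)", len(on_loss), min_snps)
        return PurityEstimate(purity=1.0, n_informative_snps=len(on_loss),
                              ci_low=1.0, ci_high=1.0,
                              method_flag="fallback_neutral")
    b = _fold(np.array([s.tumor_alt_fraction for s in on_loss]))
    p_hat = purity_from_folded(b)
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        boots[i] = purity_from_folded(
            b[rng.integers(0, len(b), size=len(b))])
    ci_low = float(np.quantile(boots, 0.025))
    ci_high = float(np.quantile(boots, 0.975))
    ci_low = min(ci_low, p_hat)
    ci_high = max(ci_high, p_hat)
    log.info("purity estimate %.3f (CI %.3f-%.3f) from %d SNPs",
             p_hat, ci_low, ci_high, len(on_loss))
    return PurityEstimate(purity=p_hat, n_informative_snps=len(on_loss),
                          ci_low=ci_low, ci_high=ci_high,
                          method_flag="informative")


def estimate_sample_purity(coverage: Sequence[CoverageRow],
                           snps: Sequence[HetSNP], config: RunConfig,
                           rng: np.random.Generator | int | None = None,
                           ) -> PurityEstimate:
    """First-pass segmentation at purity 1, then allelic inversion.

    This is the entry point used by the pipeline: it filters regions,
    segments the raw log2 profile, selects hemizygous-loss candidates
    and estimates purity from the informative SNPs above them.
    """
    from .scna import filter_regions  # local import to avoid cycle noise

    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    kept = filter_regions(coverage, config.region_min_cov,
                          config.region_filter_mode)
    profile = compute_log2(kept, purity=1.0)
    segments = segment_cbs(profile, alpha=config.cbs_alpha,
                           nperm=config.cbs_nperm,
                           min_width=config.cbs_min_width, rng=rng,
                           merge_delta=config.cbs_merge_delta,
                           use_corrected=False)
    candidates = candidate_loss_segments(
        segments, config.purity_candidate_log2_low,
        config.purity_candidate_log2_high)
    informative = select_informative_snps(snps, config.purity_min_depth)
    return estimate_purity(informative, candidates, rng=rng,
                           n_bootstrap=config.purity_n_bootstrap,
                           min_snps=config.purity_min_snps)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

PURITY_COLUMNS = ("sample_id", "purity", "n_informative_snps", "ci_low",
                  "ci_high", "method_flag")


def write_purity_table(estimates: dict[str, PurityEstimate],
                       path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PURITY_COLUMNS)
        for sid in sorted(estimates):
            e = estimates[sid]
            w.writerow([sid, f"{e.purity:.6f}", e.n_informative_snps,
                        f"{e.ci_low:.6f}", f"{e.ci_high:.6f}",
                        e.method_flag])


def read_purity_table(path: str | Path) -> dict[str, PurityEstimate]:
    out: dict[str, PurityEstimate] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            out[rec["sample_id"]] = PurityEstimate(
                purity=float(rec["purity"]),
                n_informative_snps=int(rec["n_informative_snps"]),
                ci_low=float(rec["ci_low"]),
                ci_high=float(rec["ci_high"]),
                method_flag=rec["method_flag"],
            )
    return out
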