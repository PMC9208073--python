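"""Somatic copy-number calling from paired tumor/normal exome coverage.

Pipeline per sample: drop poorly covered capture regions, form
normalized tumor/normal log2 ratios, segment each chromosome with
circular binary segmentation (CBS), rescale each segment's mean ratio
to the pure-tumor scale given purity, classify segments into five
classes against fixed log2 thresholds, annotate cytobands and flag
samples whose genome is mostly non-neutral for manual ploidy review.

The purity correction r' = (r - (1 - p)) / p is applied to *segment
mean* ratios rather than region-by-region: per-region corrected ratios
have their noise amplified by 1/p and, below roughly 50% purity, a
sizable fraction of regions inside a true loss land at or below zero,
so flooring and log-transforming them region-wise biases segment means
far below the truth.  Segment means estimated on the raw scale are
stable, and correcting them keeps the +-0.5 / +-1 call thresholds
anchored to integer copy number in a pure tumor.

The CBS here is a permutation-tested variant of the classical recursive
scheme: on each chromosome the arc (i, j] maximizing a t-like contrast
between the arc and its complement is found exhaustively; the split is
accepted when its permutation p-value falls below ``alpha``, and the
recursion continues on the resulting pieces.  Adjacent segments whose
means differ by less than a merge threshold are fused afterwards, which
also guards against spurious micro-splits on flat profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CaptureRegion,
    CoverageRow,
    Cytoband,
    RunConfig,
    SEX_CHROMOSOMES,
    Segment,
    chrom_rank,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# region filtering and log2 ratios
# ---------------------------------------------------------------------------

def filter_regions(rows: Sequence[CoverageRow], min_cov: int = 100,
                   mode: str = "and") -> list[CoverageRow]:
    """Drop capture regions with insufficient coverage.

    With ``mode="and"`` (default) a region is excluded only when **both**
    tumor and normal counts fall below ``min_cov``; ``mode="or"``
    excludes a region when either does.  Raises if nothing survives.
    """
    if mode == "and":
        kept = [r for r in rows if not (r.tumor_reads < min_cov
                                        and r.normal_reads < min_cov)]
    elif mode == "or":
        kept = [r for r in rows if r.tumor_reads >= min_cov
                and r.normal_reads >= min_cov]
    else:
        raise ValueError("mode must be 'and' or 'or'")
    if rows and not kept:
        raise ValueError("all capture regions failed the coverage filter")
    log.info("region filter (%s, <%d): kept %d / %d", mode, min_cov,
             len(kept), len(rows))
    return kept


@dataclass
class Log2Profile:
    """Per-region log2 coverage ratios, raw and purity-corrected."""

    regions: list[CaptureRegion]
    log2_raw: np.ndarray
    log2_corrected: np.ndarray


def compute_log2(rows: Sequence[CoverageRow], purity: float,
                 ratio_floor: float = 0.01) -> Log2Profile:
    """Normalized, purity-corrected log2 tumor/normal coverage ratios.

    Each sample's counts are normalized to its own total; the ratio
    r = (tumor/tumor_total) / (normal/normal_total) is rescaled to the
    pure-tumor scale by r' = (r - (1 - purity)) / purity, floored at
    ``ratio_floor`` so log2 stays finite.  At purity 1 the corrected
    profile equals the raw one.  Retained regions with zero normal reads
    are dropped with a warning.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    usable = [r for r in rows if r.normal_reads > 0]
    n_dropped = len(rows) - len(usable)
    if n_dropped:
        log.warning("dropped %d regions with zero normal reads", n_dropped)
    if not usable:
        raise ValueError("no regions with nonzero normal coverage")
    tumor = np.array([r.tumor_reads for r in usable], dtype=float)
    normal = np.array([r.normal_reads for r in usable], dtype=float)
    ratio = (tumor / tumor.sum()) / (normal / normal.sum())
    ratio = np.maximum(ratio, ratio_floor)
    corrected = np.maximum((ratio - (1.0 - purity)) / purity, ratio_floor)
    return Log2Profile(
        regions=[r.region for r in usable],
        log2_raw=np.log2(ratio),
        log2_corrected=np.log2(corrected),
    )


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------

def _arc_pairs(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) arc bounds with arc and complement >= min_width."""
    i, j = np.triu_indices(n + 1, k=min_width)
    keep = (j - i) <= n - min_width
    return i[keep], j[keep]


def _max_arc_stat(x: np.ndarray, ii: np.ndarray, jj: np.ndarray,
                  s: float) -> tuple[float, int, int]:
    """Maximum |t|-like arc-vs-complement statistic and its argmax."""
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    total = cs[-1]
    k = (jj - ii).astype(float)
    d = cs[jj] - cs[ii]
    diff = d / k - (total - d) / (n - k)
    t = np.abs(diff) / (s * np.sqrt(1.0 / k + 1.0 / (n - k)))
    a = int(np.argmax(t))
    return float(t[a]), int(ii[a]), int(jj[a])


def _perm_exceedances(x: np.ndarray, ii: np.ndarray, jj: np.ndarray,
                      s: float, t_obs: float, nperm: int, alpha: float,
                      rng: np.random.Generator) -> tuple[int, int]:
    """Count permutations whose max arc statistic reaches ``t_obs``.

    Stops early once the count can no longer yield p < alpha.  Returns
    (exceedances, permutations evaluated).
    """
    n = len(x)
    k = (jj - ii).astype(float)
    denom = s * np.sqrt(1.0 / k + 1.0 / (n - k))
    stop_at = int(np.floor(alpha * (nperm + 1)))  # exceed => p >= alpha
    exceed = 0
    done = 0
    # small chunks let clearly-null splits stop after ~one chunk while
    # keeping each chunk big enough to amortize the vectorized work
    chunk = int(np.clip(2_000_000 // max(len(ii), 1), 32, 125))
    while done < nperm:
        b = min(chunk, nperm - done)
        perms = rng.permuted(np.broadcast_to(x, (b, n)), axis=1)
        cs = np.concatenate([np.zeros((b, 1)), np.cumsum(perms, axis=1)],
                            axis=1)
        total = cs[:, -1:]
        d = cs[:, jj] - cs[:, ii]
        diff = d / k - (total - d) / (n - k)
        tmax = np.max(np.abs(diff) / denom, axis=1)
        exceed += int(np.sum(tmax >= t_obs))
        done += b
        if exceed >= stop_at:
            break
    return exceed, done


def _segment_bounds(x: np.ndarray, alpha: float, nperm: int,
                    min_width: int, rng: np.random.Generator) -> list[int]:
    """Recursive CBS change-point search; returns sorted split indices."""
    n = len(x)
    if n < 2 * min_width:
        return []
    s = float(np.std(x, ddof=1))
    if s <= 1e-12:
        return []
    ii, jj = _arc_pairs(n, min_width)
    t_obs, bi, bj = _max_arc_stat(x, ii, jj, s)
    exceed, done = _perm_exceedances(x, ii, jj, s, t_obs, nperm, alpha, rng)
    p = (1 + exceed) / (1 + done)
    if p >= alpha:
        return []
    splits = sorted({bi, bj} - {0, n})
    out: list[int] = list(splits)
    edges = [0] + splits + [n]
    for a, b in zip(edges[:-1], edges[1:]):
        out.extend(a + s_ for s_ in _segment_bounds(
            x[a:b], alpha, nperm, min_width, rng))
    return sorted(set(out))


def _merge_adjacent(bounds: list[int], x: np.ndarray,
                    delta: float) -> list[int]:
    """Fuse neighboring segments whose means differ by less than delta."""
    bounds = list(bounds)
    while bounds:
        edges = [0] + bounds + [len(x)]
        means = [x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
        gaps = [abs(means[i + 1] - means[i]) for i in range(len(means) - 1)]
        i = int(np.argmin(gaps))
        if gaps[i] >= delta:
            break
        bounds.pop(i)
    return bounds


def segment_cbs(profile: Log2Profile, alpha: float = 0.01,
                nperm: int = 1000, min_width: int = 3,
                rng: np.random.Generator | int | None = None,
                merge_delta: float = 0.1,
                use_corrected: bool = False) -> list[Segment]:
    """Segment a log2 profile chromosome by chromosome with CBS.

    Each segment's ``seg_mean`` is the arithmetic mean of its member
    log2 values; chromosomes shorter than ``2 * min_width`` regions form
    a single segment.  The permutation test is seeded through ``rng``
    for reproducibility.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    values = profile.log2_corrected if use_corrected else profile.log2_raw
    segments: list[Segment] = []
    order = np.argsort([chrom_rank(r.chrom) for r in profile.regions],
                       kind="stable")
    regions = [profile.regions[i] for i in order]
    values = np.asarray(values)[order]
    chroms = [r.chrom for r in regions]
    for chrom in sorted(set(chroms), key=chrom_rank):
        idx = [i for i, c in enumerate(chroms) if c == chrom]
        x = values[idx]
        regs = [regions[i] for i in idx]
        bounds = _segment_bounds(x, alpha, nperm, min_width, rng)
        bounds = _merge_adjacent(bounds, x, merge_delta)
        edges = [0] + bounds + [len(x)]
        for a, b in zip(edges[:-1], edges[1:]):
            member = regs[a:b]
            segments.append(Segment(
                chrom=chrom,
                start=member[0].start,
                end=member[-1].end,
                n_regions=b - a,
                seg_mean=float(np.mean(x[a:b])),
                region_bp=int(sum(r.length for r in member)),
            ))
    return segments


# ---------------------------------------------------------------------------
# classification, annotation, burden
# ---------------------------------------------------------------------------

def correct_segment_means(segments: Iterable[Segment], purity: float,
                          ratio_floor: float = 0.01) -> None:
    """Rescale segment mean log2 ratios to the pure-tumor scale in place.

    seg_mean' = log2(max((2**seg_mean - (1 - p)) / p, floor)).  At
    purity 1 this is the identity; a one-copy loss observed at r = 0.75
    with purity 0.5 is restored to log2 = -1 (deletion-scale in a pure
    tumor is loss of the single remaining copy's partner).
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    for s in segments:
        r = 2.0 ** s.seg_mean
        s.seg_mean = float(np.log2(
            max((r - (1.0 - purity)) / purity, ratio_floor)))


def classify_segment(seg_mean: float, config: RunConfig) -> str:
    """Five-class call from a segment mean log2 ratio.

    amplified: log2 > 1; gain: (0.5, 1]; neutral: [-0.5, 0.5];
    loss: [-1, -0.5); deletion: log2 < -1 (default thresholds).
    """
    if seg_mean > config.log2_amp:
        return "amplified"
    if seg_mean > config.log2_gain:
        return "gain"
    if seg_mean >= config.log2_loss:
        return "neutral"
    if seg_mean >= config.log2_del:
        return "loss"
    return "deletion"


def classify_segments(segments: Iterable[Segment],
                      config: RunConfig) -> None:
    for s in segments:
        s.call = classify_segment(s.seg_mean, config)


def annotate_cytobands(segments: Iterable[Segment],
                       cytobands: Sequence[Cytoband]) -> None:
    """Attach overlapped cytoband labels to each segment, in order."""
    for seg in segments:
        hits = [b for b in cytobands
                if b.chrom == seg.chrom and b.start < seg.end
                and seg.start < b.end]
        hits.sort(key=lambda b: b.start)
        names: list[str] = []
        for b in hits:
            if b.name not in names:
                names.append(b.name)
        seg.cytobands = names


@dataclass
class CnaBurden:
    """Fraction of retained capture-region bp lying in non-neutral
    segments."""

    altered_bp: int
    total_bp: int

    @property
    def fraction_altered(self) -> float:
        return self.altered_bp / self.total_bp if self.total_bp else 0.0


def cna_burden(segments: Sequence[Segment],
               include_sex: bool = False) -> CnaBurden:
    """Copy-number alteration burden over a sample's segments.

    Sex chromosomes are excluded by default because the single-copy male
    X breaks the diploid baseline.
    """
    altered = total = 0
    for s in segments:
        if not include_sex and s.chrom in SEX_CHROMOSOMES:
            continue
        bp = s.region_bp or (s.end - s.start)
        total += bp
        if s.call != "neutral":
            altered += bp
    return CnaBurden(altered_bp=altered, total_bp=total)


def needs_ploidy_review(segments: Sequence[Segment],
                        include_sex: bool = False,
                        threshold: float = 0.5) -> bool:
    """Flag samples whose genome is mostly non-neutral (possible ploidy
    shift or normalization failure); flag only, no auto-correction."""
    return cna_burden(segments, include_sex=include_sex).fraction_altered \
        > threshold


def call_sample(rows: Sequence[CoverageRow], purity: float,
                cytobands: Sequence[Cytoband], config: RunConfig,
                rng: np.random.Generator | int | None = None,
                ) -> list[Segment]:
    """Full per-sample SCNA calling: filter, log2, CBS on the raw
    profile, purity-correct segment means, classify, annotate."""
    kept = filter_regions(rows, config.region_min_cov,
                          config.region_filter_mode)
    profile = compute_log2(kept, purity)
    segments = segment_cbs(profile, alpha=config.cbs_alpha,
                           nperm=config.cbs_nperm,
                           min_width=config.cbs_min_width, rng=rng,
                           merge_delta=config.cbs_merge_delta,
                           use_corrected=False)
    correct_segment_means(segments, purity)
    classify_segments(segments, config)
    annotate_cytobands(segments, cytobands)
    return segments


# ---------------------------------------------------------------------------
# cohort recurrence
# ---------------------------------------------------------------------------

def cohort_recurrence(patient_segments: Mapping[str, Sequence[Sequence[Segment]]],
                      cytobands: Sequence[Cytoband]) -> pd.DataFrame:
    """Per-cytoband counts of patients carrying a loss or a gain.

    ``patient_segments`` maps patient id to that patient's per-sample
    segment lists.  A patient counts once for a band when **any** of
    their samples has a segment overlapping the band called
    loss/deletion (column ``loss_patients``) or gain/amplified
    (``gain_patients``).
    """
    names: list[str] = []
    for b in cytobands:
        if b.name not in names:
            names.append(b.name)
    loss_counts = dict.fromkeys(names, 0)
    gain_counts = dict.fromkeys(names, 0)
    for pid in sorted(patient_segments):
        lost: set[str] = set()
        gained: set[str] = set()
        for sample_segs in patient_segments[pid]:
            for seg in sample_segs:
                if seg.call == "neutral":
                    continue
                for b in cytobands:
                    if not seg.overlaps(b.chrom, b.start, b.end):
                        continue
                    if seg.call in ("loss", "deletion"):
                        lost.add(b.name)
                    elif seg.call in ("gain", "amplified"):
                        gained.add(b.name)
        for name in lost:
            loss_counts[name] += 1
        for name in gained:
            gain_counts[name] += 1
    return pd.DataFrame({
        "cytoband": names,
        "loss_patients": [loss_counts[n] for n in names],
        "gain_patients": [gain_counts[n] for n in names],
    })
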