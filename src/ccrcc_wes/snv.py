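"""Somatic variant filtering, purity-corrected VAF, COSMIC rescue, TMB.

Filtering applies, in fixed precedence, the rules used for paired
tumor/normal exomes in metastatic ccRCC: variants detected in the
matched normal are germline and dropped; synonymous point mutations are
dropped; a variant needs at least 10 aligned tumor reads at its locus;
and the purity-corrected VAF must reach 10%.  A variant failing only
the corrected-VAF rule is rescued when it is a recurrent COSMIC
mutation (>= 10 reports) with corrected tumor VAF > 5% and normal VAF
< 1%.

The corrected VAF rescales the observed alt fraction to a hypothetical
pure tumor given purity p and local total copy number CN:

    VAF_corr = min(1, VAF_raw * (p*CN + 2*(1-p)) / (p*CN))

with mutation multiplicity 1 by default; the multiplicity is promoted
to CN when the raw VAF exceeds the multiplicity-1 ceiling by more than
two binomial standard deviations (LOH-locked mutations).

TMB is the number of kept non-synonymous mutations divided by the
megabases of genome covered (capture regions passing the coverage
filter); each event counts once regardless of its base length.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .io_formats import CoverageRow, RunConfig, Segment, VariantCall
from .scna import filter_regions

log = logging.getLogger(__name__)


def correct_vaf(vaf_raw: float, purity: float, local_cn: int,
                multiplicity: int = 1) -> float:
    """Purity/copy-number rescaled VAF, capped at 1.

    Maps the observed alt fraction to the fraction a pure tumor would
    show: VAF_corr = min(1, VAF_raw * (p*CN + 2*(1-p)) / (p*CN)).  The
    scale factor is independent of mutation multiplicity (a multiplicity
    m mutation maps to m/CN); the parameter is accepted for interface
    symmetry with the clonality computation and validated only.  At
    purity 1 this is the identity.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if local_cn < 1:
        raise ValueError(
            "local copy number 0 at a variant site is inconsistent input")
    if not 1 <= multiplicity <= local_cn:
        raise ValueError("multiplicity must lie in [1, local_cn]")
    scale = (purity * local_cn + 2.0 * (1.0 - purity)) / (purity * local_cn)
    return min(1.0, vaf_raw * scale)


def local_copy_number(call: VariantCall,
                      segments: Sequence[Segment] | None) -> int:
    """Integer CN at a variant locus from the corrected segment mean.

    Unsegmented territory is diploid.  Deletion-called segments imply
    CN 0, which is inconsistent with observing the variant; the lookup
    clamps to 1 for VAF correction (the phylogeny stage treats such loci
    as missing data instead)."""
    if not segments:
        return 2
    for seg in segments:
        if seg.overlaps(call.chrom, call.pos - 1, call.pos):
            return max(1, round(2.0 * 2.0 ** seg.seg_mean))
    return 2


def infer_multiplicity(call: VariantCall, purity: float,
                       local_cn: int) -> int:
    """Multiplicity 1 unless the raw VAF clearly exceeds the
    multiplicity-1 ceiling, in which case the mutation occupies all
    local copies (LOH-locked)."""
    if local_cn <= 1:
        return 1
    vmax = purity / (purity * local_cn + 2.0 * (1.0 - purity))
    depth = call.tumor_depth
    if depth <= 0:
        return 1
    sd = math.sqrt(max(vmax * (1.0 - vmax), 0.0) / depth)
    return local_cn if call.vaf_raw > vmax + 2.0 * sd else 1


def cosmic_rescue(call: VariantCall, config: RunConfig,
                  corrected_vaf: float) -> bool:
    """True iff a low-VAF drop qualifies for the COSMIC rescue rule:
    reported >= 10 times, corrected tumor VAF > 5%, normal VAF < 1%."""
    return (call.cosmic_count >= config.cosmic_min_reports
            and corrected_vaf > config.cosmic_tumor_vaf
            and call.normal_vaf < config.cosmic_normal_vaf)


def _in_normal(call: VariantCall, config: RunConfig) -> bool:
    return (call.normal_alt_reads >= config.normal_presence_min_reads
            and call.normal_vaf >= config.normal_presence_vaf)


def filter_variants(calls: Sequence[VariantCall], purity: float,
                    segments: Sequence[Segment] | None,
                    config: RunConfig) -> list[VariantCall]:
    """Apply the somatic filter chain in place and return the calls.

    Every input call comes back exactly once with ``filter_status``
    either ``keep`` or ``drop_<reason>``; reason precedence is
    in_normal -> synonymous -> low_reads -> low_corrected_vaf, and the
    COSMIC rescue may flip low_corrected_vaf drops back to keep.
    Per-reason counts are logged.
    """
    counts: Counter[str] = Counter()
    for call in calls:
        cn = local_copy_number(call, segments)
        mult = infer_multiplicity(call, purity, cn)
        call.vaf_corrected = correct_vaf(call.vaf_raw, purity, cn, mult)
        call.rescued_by_cosmic = False
        if _in_normal(call, config):
            call.filter_status = "drop_in_normal"
        elif call.effect == "synonymous":
            call.filter_status = "drop_synonymous"
        elif call.tumor_depth < config.min_var_reads:
            call.filter_status = "drop_low_reads"
        elif call.vaf_corrected < config.min_corrected_vaf:
            if cosmic_rescue(call, config, call.vaf_corrected):
                call.filter_status = "keep"
                call.rescued_by_cosmic = True
            else:
                call.filter_status = "drop_low_corrected_vaf"
        else:
            call.filter_status = "keep"
        counts[call.filter_status] += 1
    log.info("variant filter: %s",
             ", ".join(f"{k}={counts[k]}" for k in sorted(counts)))
    return list(calls)


@dataclass
class TmbResult:
    """Tumor mutational burden and indel fraction for one sample."""

    n_nonsynonymous: int
    covered_mb: float
    tmb: float
    indel_fraction: float


def compute_tmb(kept_calls: Sequence[VariantCall],
                coverage_rows: Sequence[CoverageRow],
                config: RunConfig) -> TmbResult:
    """Mutations per megabase over the well-covered capture territory.

    ``kept_calls`` may contain dropped records; only status ``keep``
    counts.  ``covered_mb`` is the summed length of capture regions
    passing the coverage filter, in Mb.
    """
    covered = filter_regions(coverage_rows, config.region_min_cov,
                             config.region_filter_mode)
    covered_mb = sum(r.region.length for r in covered) / 1e6
    if covered_mb <= 0:
        raise ValueError("covered territory is empty; cannot compute TMB")
    kept = [c for c in kept_calls if c.kept]
    n_nonsyn = sum(1 for c in kept if c.is_nonsynonymous)
    n_indel = sum(1 for c in kept if c.is_indel)
    return TmbResult(
        n_nonsynonymous=n_nonsyn,
        covered_mb=covered_mb,
        tmb=n_nonsyn / covered_mb,
        indel_fraction=n_indel / len(kept) if kept else 0.0,
    )
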