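"""Synthetic multi-region ccRCC cohort generator.

Emits, for a configurable number of patients, the full set of observed
tables the pipeline consumes (paired tumor/normal coverage per capture
region, MAF-like variant tables, heterozygous-SNP allelic fractions,
sample metadata, a cytoband table and a COSMIC-count lookup) together
with the generating truth (per-patient sample tree, per-edge SNV
assignments, per-sample purity and integer copy-number segments).

The statistical model mirrors the assumptions of the downstream
analysis.  Each patient carries a clonal tree of samples rooted at the
germline; SNVs are assigned to tree edges (truncal / branch / private)
with Poisson counts.  Read counts are binomial at the expected variant
allele fraction

    E[VAF] = clonality * purity * multiplicity
             / (purity * CN + 2 * (1 - purity))

given per-sample purity, local total copy number CN and mutation
multiplicity.  Coverage is negative-binomial around
``depth * (purity * CN + 2 * (1 - purity)) / 2``, i.e. overdispersed
relative to Poisson as exome coverage is in practice.  Recurrent
segmental events are planted at the cytobands recurrently altered in
metastatic ccRCC (3p25, 9p21, 14q25, 6p21, 13q14 and 5q gain) at
cohort frequencies matching those observed clinically.

The genome is a simplified exome: a configurable number of capture
regions per autosome on a 100-Mb synthetic chromosome scaffold, with
named cytobands carved out where driver events live and known ccRCC
genes placed at fixed loci (e.g. VHL inside 3p25, RB1 inside 13q14).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    AUTOSOMES,
    CaptureRegion,
    CoverageRow,
    Cytoband,
    HetSNP,
    SampleMeta,
    VariantCall,
    karyotypic_key,
    write_cosmic_table,
    write_coverage_table,
    write_cytoband_bed,
    write_het_snp_table,
    write_sample_metadata,
    write_variant_table,
)

log = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")

#: integer total copy number implied by each event class
EVENT_CN: dict[str, int] = {
    "deletion": 0,
    "loss": 1,
    "gain": 3,
    "amplification": 5,
}

#: recurrent segmental events and their patient-level probabilities,
#: matching the loss/gain frequencies reported for metastatic ccRCC
#: (e.g. 3p25 loss in 36/44 patients).
DEFAULT_DRIVER_CNV_MENU: tuple[tuple[str, str, float], ...] = (
    ("3p25", "loss", 36 / 44),
    ("9p21", "loss", 30 / 44),
    ("14q25", "loss", 17 / 44),
    ("6p21", "deletion", 18 / 44),
    ("13q14", "loss", 23 / 44),
    ("5q", "gain", 21 / 44),
)

#: patient-level mutation probabilities of the recurrently mutated genes
DEFAULT_GENE_PANEL: dict[str, float] = {
    "SETD2": 0.62,
    "PBRM1": 0.57,
    "APC": 0.43,
    "VHL": 0.36,
    "KDM5C": 0.31,
    "HIF1A": 0.24,
    "RBM10": 0.21,
    "FBXW7": 0.19,
    "TRAK1": 0.16,
    "EGFR": 0.09,
    "TP53": 0.07,
    "PTEN": 0.05,
    "CCND3": 0.05,
    "PDGFRB": 0.05,
}

#: gene placements on the synthetic 100-Mb chromosome scaffold.  VHL sits
#: inside the 3p25 band, CDKN2A inside 9p21, RB1 inside 13q14, CDKN1A
#: inside 6p21 and HIF1A inside 14q25; the rest are arbitrary but fixed.
GENE_LOCI: dict[str, tuple[str, int]] = {
    "VHL": ("3", 5_000_000),
    "SETD2": ("3", 20_000_000),
    "PBRM1": ("3", 30_000_000),
    "TRAK1": ("3", 40_000_000),
    "FBXW7": ("4", 60_000_000),
    "APC": ("5", 60_000_000),
    "PDGFRB": ("5", 80_000_000),
    "CDKN1A": ("6", 5_000_000),
    "CCND3": ("6", 30_000_000),
    "EGFR": ("7", 20_000_000),
    "CDKN2A": ("9", 5_000_000),
    "PTEN": ("10", 70_000_000),
    "RBM10": ("11", 20_000_000),
    "KDM5C": ("12", 20_000_000),
    "RB1": ("13", 55_000_000),
    "HIF1A": ("14", 95_000_000),
    "TP53": ("17", 5_000_000),
}

_METASTATIC_SITES = ("lung", "bone", "lymph_node", "brain", "soft_tissue",
                     "liver", "adrenal")


@dataclass
class SimConfig:
    """Tunable simulation parameters with cohort-scale defaults.

    Defaults reproduce the shape of a 44-patient metastatic ccRCC WES
    cohort: 13 patients contribute 2-4 multi-region samples (~68 samples
    in total), mean capture-region depth 100x, 334 heterozygous SNPs per
    sample, and driver copy-number events at the recurrent cytobands at
    their observed cohort frequencies.
    """

    n_patients: int = 44
    n_multi_sample_patients: int = 13
    multi_sample_range: tuple[int, int] = (2, 4)
    purity_range: tuple[float, float] = (0.2, 0.9)
    mean_region_depth: float = 100.0
    coverage_dispersion: float = 300.0  # negative-binomial size parameter
    n_truncal_snvs: float = 40.0  # Poisson means per tree edge class
    n_branch_snvs: float = 15.0
    n_private_snvs: float = 8.0
    driver_cnv_menu: tuple[tuple[str, str, float], ...] = (
        DEFAULT_DRIVER_CNV_MENU)
    truncal_cnv_prob: float = 0.8
    snv_gene_panel: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_PANEL))
    driver_snv_truncal_prob: float = 0.8
    vhl_pathway_truncal_prob: float = 0.9
    pretreated_fraction: float = 38 / 68
    synonymous_fraction: float = 0.25
    germline_leak_rate: float = 0.02
    normal_error_rate: float = 0.002
    n_het_snps: int = 334
    hotspot_subclonal_mean: float = 1.0
    subclonal_clonality: float = 0.15
    treatment_vaf_shift: Mapping[str, float] = field(default_factory=dict)
    effect_probs: Mapping[str, float] = field(default_factory=lambda: {
        "missense": 0.62, "nonsense": 0.12, "frameshift_indel": 0.12,
        "inframe_indel": 0.04, "splice": 0.10})
    arm_scale_events: bool = True
    n_regions_per_chrom: int = 80
    region_length: int = 5000
    chrom_length: int = 100_000_000
    chroms: tuple[str, ...] = AUTOSOMES
    rng_seed: int = 0

    def __post_init__(self):
        if self.mean_region_depth <= 0:
            raise ValueError("mean_region_depth must be positive")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must lie in (0, 1]")
        for _, event, prob in self.driver_cnv_menu:
            if event not in EVENT_CN:
                raise ValueError(f"unknown CNV event class {event!r}")
            if not 0 <= prob <= 1:
                raise ValueError("event probabilities must lie in [0, 1]")
        for prob in self.snv_gene_panel.values():
            if not 0 <= prob <= 1:
                raise ValueError("gene panel probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# reference scaffold
# ---------------------------------------------------------------------------

# special named bands carved out of the generic per-arm bands
_SPECIAL_BANDS: tuple[tuple[str, str, int, int], ...] = (
    ("3p25", "3", 0, 10_000_000),
    ("9p21", "9", 0, 10_000_000),
    ("6p21", "6", 0, 10_000_000),
    ("13q14", "13", 50_000_000, 60_000_000),
    ("14q25", "14", 90_000_000, 100_000_000),
)


def build_cytobands(chroms: Sequence[str] = AUTOSOMES,
                    chrom_length: int = 100_000_000) -> list[Cytoband]:
    """Cytoband table for the synthetic genome: one p and one q band per
    chromosome, with the driver bands carved out as separate intervals."""
    half = chrom_length // 2
    bands: list[Cytoband] = []
    for c in chroms:
        carve = [(n, s, e) for n, cc, s, e in _SPECIAL_BANDS if cc == c
                 and e <= chrom_length]
        arms = [(f"{c}p", 0, half), (f"{c}q", half, chrom_length)]
        if c == "5":
            # whole q arm treated as the recurrent 5q gain territory
            arms = [("5p", 0, half), ("5q", half, chrom_length)]
        for arm_name, a_start, a_end in arms:
            cuts = sorted([(s, e, n) for n, s, e in carve
                           if s >= a_start and e <= a_end])
            pos = a_start
            for s, e, n in cuts:
                if pos < s:
                    bands.append(Cytoband(c, pos, s, arm_name))
                bands.append(Cytoband(c, s, e, n))
                pos = e
            if pos < a_end:
                bands.append(Cytoband(c, pos, a_end, arm_name))
    bands.sort(key=lambda b: karyotypic_key(b.chrom, b.start, b.end))
    return bands


def build_reference(config: SimConfig) -> tuple[list[CaptureRegion],
                                                list[Cytoband]]:
    """Capture regions (evenly spaced) plus the cytoband table."""
    bands = build_cytobands(config.chroms, config.chrom_length)
    gene_at: dict[tuple[str, int], str] = {}
    spacing = config.chrom_length // config.n_regions_per_chrom
    for gene, (chrom, pos) in GENE_LOCI.items():
        if chrom in config.chroms:
            gene_at[(chrom, pos // spacing)] = gene
    regions: list[CaptureRegion] = []
    for c in config.chroms:
        c_bands = [b for b in bands if b.chrom == c]
        for i in range(config.n_regions_per_chrom):
            start = i * spacing
            end = start + config.region_length
            mid = (start + end) // 2
            band = next((b.name for b in c_bands
                         if b.start <= mid < b.end), "")
            gene = gene_at.get((c, i), f"G{c}R{i:02d}")
            regions.append(CaptureRegion(c, start, end, gene, band))
    regions.sort(key=lambda r: r.sort_key)
    return regions, bands


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class TrueSNV:
    """One simulated somatic SNV/indel and its generating parameters."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    clade: frozenset
    clonality: float = 1.0
    cosmic_count: int = 0
    germline_leak: bool = False
    normal_depth: int = 0
    normal_alt: int = 0

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TrueEvent:
    """One simulated segmental copy-number event."""

    cytoband: str
    chrom: str
    start: int
    end: int
    event: str
    clade: frozenset

    @property
    def cn(self) -> int:
        return EVENT_CN[self.event]


@dataclass
class PatientTruth:
    patient_id: str
    sample_ids: list[str]
    clades: list[frozenset]  # laminar family incl. full set and singletons
    edge_counts: dict[frozenset, int]  # background SNVs drawn per edge
    snvs: list[TrueSNV]
    events: list[TrueEvent]
    purity: dict[str, float]
    meta: list[SampleMeta]

    def sample_segments(self, sample_id: str) -> list[tuple[str, int, int, int]]:
        """True (chrom, start, end, CN) events carried by one sample."""
        return [(e.chrom, e.start, e.end, e.cn) for e in self.events
                if sample_id in e.clade]

    def nontrivial_clades(self) -> set[frozenset]:
        n = len(self.sample_ids)
        return {c for c in self.clades if 1 < len(c) < n}

    def truncal_snv_count(self) -> int:
        """Clonal truncal SNVs the somatic filters should retain
        (non-synonymous, not leaked into the matched normal)."""
        full = frozenset(self.sample_ids)
        return sum(1 for s in self.snvs
                   if s.clade == full and s.clonality >= 1.0
                   and s.effect != "synonymous" and not s.germline_leak)


@dataclass
class SyntheticTruth:
    config: SimConfig
    regions: list[CaptureRegion]
    cytobands: list[Cytoband]
    patients: dict[str, PatientTruth]


# ---------------------------------------------------------------------------
# elementary samplers
# ---------------------------------------------------------------------------

def expected_vaf(clonality: float, purity: float, local_cn: int,
                 multiplicity: int) -> float:
    """Expected variant allele fraction under the admixture model."""
    den = purity * local_cn + 2.0 * (1.0 - purity)
    if den <= 0:
        return 0.0
    return clonality * purity * multiplicity / den


def expected_coverage_ratio(purity: float, cn: int) -> float:
    """Expected tumor/normal coverage ratio over a CN segment."""
    return (purity * cn + 2.0 * (1.0 - purity)) / 2.0


def expected_het_fraction(purity: float, cn: int, alt_copies: int) -> float:
    """Expected tumor alt fraction of a germline-het SNP whose alt allele
    carries ``alt_copies`` of the ``cn`` tumor copies."""
    den = purity * cn + 2.0 * (1.0 - purity)
    if den <= 0:
        return 0.5
    return (purity * alt_copies + (1.0 - purity)) / den


def _nbinom(rng: np.random.Generator, mean, size: float):
    """Negative-binomial draws with the given mean and size (dispersion)
    parameter; ``size = inf`` degrades to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if not np.isfinite(size):
        return rng.poisson(mean)
    p = size / (size + np.maximum(mean, 0.0))
    return rng.negative_binomial(size, p)


def _cn_at(segments: Iterable[tuple[str, int, int, int]], chrom: str,
           pos: int) -> int:
    for c, s, e, cn in segments:
        if c == chrom and s <= pos < e:
            return cn
    return 2


def simulate_coverage(regions: Sequence[CaptureRegion],
                      true_segments: Sequence[tuple[str, int, int, int]],
                      purity: float, depth: float, dispersion: float,
                      rng: np.random.Generator) -> list[CoverageRow]:
    """Overdispersed paired read counts per capture region.

    ``true_segments`` are (chrom, start, end, CN) tuples; unlisted
    territory is diploid.  Tumor means follow the admixture coverage
    ratio; both samples draw from a negative binomial with the given
    dispersion (size) parameter.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    cns = np.array([_cn_at(true_segments, r.chrom, (r.start + r.end) // 2)
                    for r in regions])
    ratio = (purity * cns + 2.0 * (1.0 - purity)) / 2.0
    normal = _nbinom(rng, np.full(len(regions), depth), dispersion)
    tumor = _nbinom(rng, depth * ratio, dispersion)
    return [CoverageRow(region=r, tumor_reads=int(t), normal_reads=int(n))
            for r, t, n in zip(regions, tumor, normal)]


def simulate_variant_reads(clonality: float, purity: float, local_cn: int,
                           multiplicity: int, depth: int,
                           rng: np.random.Generator,
                           error_rate: float = 0.002,
                           ) -> tuple[int, int, int, int]:
    """Binomial tumor/normal read support for one variant.

    Returns (tumor_ref, tumor_alt, normal_ref, normal_alt).
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if multiplicity > local_cn:
        raise ValueError("multiplicity cannot exceed local copy number")
    v = expected_vaf(clonality, purity, local_cn, multiplicity)
    tumor_alt = int(rng.binomial(depth, min(v, 1.0)))
    normal_alt = int(rng.binomial(depth, error_rate))
    return depth - tumor_alt, tumor_alt, depth - normal_alt, normal_alt


def simulate_het_snps(true_segments: Sequence[tuple[str, int, int, int]],
                      purity: float, n_snps: int, depth: float,
                      rng: np.random.Generator,
                      regions: Sequence[CaptureRegion]) -> list[HetSNP]:
    """Heterozygous-SNP allelic fractions for one sample.

    SNPs are placed uniformly over capture regions; the tumor alt
    fraction is binomial around the allele-mixture expectation of the
    overlying true segment, with the alt allele assigned to either
    haplotype with equal probability.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    idx = rng.integers(0, len(regions), size=n_snps)
    snps: list[HetSNP] = []
    for i in idx:
        r = regions[int(i)]
        pos = int(r.start + 1 + rng.integers(0, r.length))
        cn = _cn_at(true_segments, r.chrom, pos)
        if cn >= 2:
            alleles = (cn - 1, 1)
        elif cn == 1:
            alleles = (1, 0)
        else:
            alleles = (0, 0)
        alt_copies = int(alleles[int(rng.integers(0, 2))])
        f_t = expected_het_fraction(purity, cn, alt_copies)
        ratio = expected_coverage_ratio(purity, cn)
        td = int(rng.poisson(depth * ratio))
        nd = int(rng.poisson(depth))
        ta = int(rng.binomial(td, f_t)) if td > 0 else 0
        na = int(rng.binomial(nd, 0.5)) if nd > 0 else 0
        snps.append(HetSNP(
            chrom=r.chrom, pos=pos,
            tumor_alt_fraction=ta / td if td > 0 else 0.0,
            normal_alt_fraction=na / nd if nd > 0 else 0.0,
            tumor_depth=td, normal_depth=nd,
        ))
    snps.sort(key=lambda s: karyotypic_key(s.chrom, s.pos))
    return snps


# ---------------------------------------------------------------------------
# patient-level simulation
# ---------------------------------------------------------------------------

def simulate_patient_tree(sample_ids: Sequence[str],
                          snv_rates: tuple[float, float, float],
                          rng: np.random.Generator,
                          ) -> tuple[list[frozenset], dict[frozenset, int]]:
    """Random clonal tree over samples with Poisson SNV counts per edge.

    ``snv_rates`` are the Poisson means for (truncal, branch, private)
    edges.  Returns the laminar clade family (including the full sample
    set and singletons) and the SNV count drawn for each clade's edge.
    A single sample yields one edge carrying the truncal count.
    """
    if len(sample_ids) == 0:
        raise ValueError("a patient needs at least one sample")
    truncal_mean, branch_mean, private_mean = snv_rates
    clades: list[frozenset] = []

    def split(group: tuple[str, ...]):
        clades.append(frozenset(group))
        if len(group) == 1:
            return
        while True:
            mask = rng.integers(0, 2, size=len(group)).astype(bool)
            if mask.any() and not mask.all():
                break
        split(tuple(s for s, m in zip(group, mask) if m))
        split(tuple(s for s, m in zip(group, mask) if not m))

    split(tuple(sorted(sample_ids)))
    full = frozenset(sample_ids)
    counts: dict[frozenset, int] = {}
    for clade in clades:
        if clade == full:
            mean = truncal_mean
        elif len(clade) == 1:
            mean = private_mean
        else:
            mean = branch_mean
        counts[clade] = int(rng.poisson(mean))
    return clades, counts


def _draw_effect(rng: np.random.Generator, config: SimConfig,
                 synonymous_allowed: bool) -> str:
    if synonymous_allowed and rng.random() < config.synonymous_fraction:
        return "synonymous"
    names = sorted(config.effect_probs)
    probs = np.array([config.effect_probs[n] for n in names], dtype=float)
    probs /= probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def _new_locus(rng: np.random.Generator, regions: Sequence[CaptureRegion],
               used: set, region=None) -> tuple[CaptureRegion, int]:
    while True:
        r = region if region is not None else (
            regions[int(rng.integers(0, len(regions)))])
        pos = int(r.start + 1 + rng.integers(0, r.length))
        if (r.chrom, pos) not in used:
            used.add((r.chrom, pos))
            return r, pos


def simulate_patient(patient_id: str, sample_ids: Sequence[str],
                     regions: Sequence[CaptureRegion],
                     cytobands: Sequence[Cytoband], config: SimConfig,
                     rng: np.random.Generator) -> PatientTruth:
    """Draw the full generating truth for one patient."""
    clades, edge_counts = simulate_patient_tree(
        sample_ids,
        (config.n_truncal_snvs, config.n_branch_snvs, config.n_private_snvs),
        rng)
    full = frozenset(sample_ids)
    used: set = set()
    snvs: list[TrueSNV] = []
    gene_regions = {r.gene: r for r in regions}

    def finish_snv(region, pos, gene, effect, clade, clonality, cosmic):
        ref = _BASES[int(rng.integers(0, 4))]
        if effect == "frameshift_indel":
            alt = ref + _BASES[int(rng.integers(0, 4))]
        elif effect == "inframe_indel":
            alt = ref + "".join(_BASES[int(b)] for b in rng.integers(0, 4, 3))
        else:
            alt = _BASES[int((int(_BASES.index(ref)) + 1
                              + rng.integers(0, 3)) % 4)]
        leak = bool(rng.random() < config.germline_leak_rate)
        nd = int(rng.poisson(config.mean_region_depth))
        p_alt = 0.5 if leak else config.normal_error_rate
        na = int(rng.binomial(nd, p_alt)) if nd > 0 else 0
        snvs.append(TrueSNV(
            chrom=region.chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            effect=effect, clade=clade, clonality=clonality,
            cosmic_count=cosmic, germline_leak=leak,
            normal_depth=nd, normal_alt=na))

    # background SNVs per tree edge
    for clade in clades:
        for _ in range(edge_counts[clade]):
            region, pos = _new_locus(rng, regions, used)
            effect = _draw_effect(rng, config, synonymous_allowed=True)
            finish_snv(region, pos, region.gene, effect, clade, 1.0, 0)

    # recurrently mutated driver genes
    for gene in sorted(config.snv_gene_panel):
        if rng.random() >= config.snv_gene_panel[gene]:
            continue
        region = gene_regions.get(gene)
        if region is None:
            continue
        region, pos = _new_locus(rng, regions, used, region=region)
        effect = ["missense", "nonsense", "frameshift_indel", "splice"][
            int(rng.choice(4, p=[0.5, 0.2, 0.2, 0.1]))]
        if rng.random() < config.driver_snv_truncal_prob or len(clades) == 1:
            clade = full
        else:
            others = sorted((c for c in clades if c != full),
                            key=lambda c: tuple(sorted(c)))
            clade = others[int(rng.integers(0, len(others)))]
        cosmic = 10 + int(rng.poisson(40))
        finish_snv(region, pos, gene, effect, clade, 1.0, cosmic)

    # low-clonality hotspot variants exercising the COSMIC rescue arm
    for _ in range(int(rng.poisson(config.hotspot_subclonal_mean))):
        region, pos = _new_locus(rng, regions, used)
        finish_snv(region, pos, region.gene, "missense", full,
                   config.subclonal_clonality, 10 + int(rng.poisson(40)))

    # segmental copy-number events at the driver cytobands
    band_by_name: dict[str, Cytoband] = {}
    for b in cytobands:
        band_by_name.setdefault(b.name, b)
    events: list[TrueEvent] = []
    half = config.chrom_length // 2

    def event_extent(band: Cytoband, event: str) -> tuple[int, int]:
        # hemizygous losses and gains are arm-scale, as they typically are
        # in ccRCC (3p, 9p, 14q...); homozygous deletions stay focal
        if not config.arm_scale_events or event == "deletion":
            return band.start, band.end
        mid = (band.start + band.end) // 2
        return (0, half) if mid < half else (half, config.chrom_length)

    for band_name, event, prob in config.driver_cnv_menu:
        if rng.random() >= prob:
            continue
        band = band_by_name[band_name]
        if rng.random() < config.truncal_cnv_prob or len(clades) == 1:
            clade = full
        else:
            others = sorted((c for c in clades if c != full),
                            key=lambda c: tuple(sorted(c)))
            clade = others[int(rng.integers(0, len(others)))]
        start, end = event_extent(band, event)
        events.append(TrueEvent(band_name, band.chrom, start, end,
                                event, clade))

    # a VHL-pathway hit (VHL mutation or 3p25 loss) is almost always truncal
    has_vhl_truncal = any(s.gene == "VHL" and s.clade == full for s in snvs)
    ev_3p = next((e for e in events if e.cytoband == "3p25"), None)
    if (not has_vhl_truncal and (ev_3p is None or ev_3p.clade != full)
            and rng.random() < config.vhl_pathway_truncal_prob):
        if ev_3p is not None:
            ev_3p.clade = full
        else:
            band = band_by_name["3p25"]
            start, end = event_extent(band, "loss")
            events.append(TrueEvent("3p25", band.chrom, start, end,
                                    "loss", full))

    lo, hi = config.purity_range
    purity = {s: float(lo + (hi - lo) * rng.random()) for s in sample_ids}
    metas = []
    for i, s in enumerate(sample_ids):
        primary = i == 0 and rng.random() < 0.5
        site = "kidney" if primary else _METASTATIC_SITES[
            int(rng.integers(0, len(_METASTATIC_SITES)))]
        metas.append(SampleMeta(
            sample_id=s, patient_id=patient_id, site=site,
            pretreated=bool(rng.random() < config.pretreated_fraction),
            tissue_type="primary" if primary else "metastasis"))
    return PatientTruth(
        patient_id=patient_id, sample_ids=list(sample_ids), clades=clades,
        edge_counts=edge_counts, snvs=snvs, events=events, purity=purity,
        meta=metas)


def simulate_sample_tables(truth: PatientTruth, sample_id: str,
                           regions: Sequence[CaptureRegion],
                           config: SimConfig, rng: np.random.Generator,
                           ) -> dict:
    """Observed coverage, variant and het-SNP tables for one sample."""
    purity = truth.purity[sample_id]
    segments = truth.sample_segments(sample_id)
    meta = next(m for m in truth.meta if m.sample_id == sample_id)
    coverage = simulate_coverage(regions, segments, purity,
                                 config.mean_region_depth,
                                 config.coverage_dispersion, rng)
    calls: list[VariantCall] = []
    for snv in truth.snvs:
        cn = _cn_at(segments, snv.chrom, snv.pos)
        present = sample_id in snv.clade
        mult = min(1, cn) if present else 0
        v = expected_vaf(snv.clonality if present else 0.0, purity, cn, mult)
        if (present and meta.pretreated
                and snv.gene in config.treatment_vaf_shift):
            v = min(0.95, max(0.0, v + config.treatment_vaf_shift[snv.gene]))
        ratio = expected_coverage_ratio(purity, cn)
        td = max(1, int(rng.poisson(config.mean_region_depth
                                    * max(ratio, 0.05))))
        ta = int(rng.binomial(td, min(v, 1.0)))
        calls.append(VariantCall(
            chrom=snv.chrom, pos=snv.pos, ref=snv.ref, alt=snv.alt,
            gene=snv.gene, effect=snv.effect,
            tumor_ref_reads=td - ta, tumor_alt_reads=ta,
            normal_ref_reads=snv.normal_depth - snv.normal_alt,
            normal_alt_reads=snv.normal_alt))
    calls.sort(key=lambda v: karyotypic_key(v.chrom, v.pos) + (v.ref, v.alt))
    hetsnps = simulate_het_snps(segments, purity, config.n_het_snps,
                                config.mean_region_depth, rng, regions)
    return {"coverage": coverage, "variants": calls, "hetsnps": hetsnps}


# ---------------------------------------------------------------------------
# cohort-level generation and emission
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig, seed: int | None = None,
                    ) -> tuple[SyntheticTruth, dict]:
    """Generate the whole cohort in memory.

    Returns the truth plus a dict with per-sample observed tables
    (``tables``), the metadata rows (``meta``) and the COSMIC lookup
    (``cosmic``).
    """
    root = np.random.SeedSequence(
        config.rng_seed if seed is None else seed)
    regions, cytobands = build_reference(config)
    n = config.n_patients
    streams = root.spawn(max(n, 1) + 1)
    layout_rng = np.random.default_rng(streams[0])
    n_multi = min(config.n_multi_sample_patients, n)
    multi_idx = set(layout_rng.choice(n, size=n_multi, replace=False).tolist()
                    ) if n else set()
    patients: dict[str, PatientTruth] = {}
    tables: dict[str, dict] = {}
    metas: list[SampleMeta] = []
    cosmic: dict[tuple, int] = {}
    for i in range(n):
        pid = f"P{i + 1:03d}"
        lo, hi = config.multi_sample_range
        k = int(layout_rng.integers(lo, hi + 1)) if i in multi_idx else 1
        sample_ids = [f"{pid}-S{j + 1}" for j in range(k)]
        rng = np.random.default_rng(streams[i + 1])
        truth = simulate_patient(pid, sample_ids, regions, cytobands,
                                 config, rng)
        patients[pid] = truth
        metas.extend(truth.meta)
        for snv in truth.snvs:
            if snv.cosmic_count > 0:
                cosmic[snv.key] = snv.cosmic_count
        for s in sample_ids:
            tables[s] = simulate_sample_tables(truth, s, regions, config,
                                               rng)
    truth_all = SyntheticTruth(config=config, regions=regions,
                               cytobands=cytobands, patients=patients)
    return truth_all, {"tables": tables, "meta": metas, "cosmic": cosmic}


def _truth_to_json(truth: SyntheticTruth) -> dict:
    out: dict = {"patients": {}}
    for pid in sorted(truth.patients):
        p = truth.patients[pid]
        out["patients"][pid] = {
            "sample_ids": sorted(p.sample_ids),
            "clades": [sorted(c) for c in sorted(
                p.clades, key=lambda c: (len(c), tuple(sorted(c))))],
            "edge_counts": {"|".join(sorted(c)): n
                            for c, n in sorted(
                                p.edge_counts.items(),
                                key=lambda kv: tuple(sorted(kv[0])))},
            "purity": {s: round(p.purity[s], 6) for s in sorted(p.purity)},
            "events": [dataclasses.asdict(e) | {"clade": sorted(e.clade)}
                       for e in p.events],
            "snvs": [dataclasses.asdict(s) | {"clade": sorted(s.clade)}
                     for s in p.snvs],
        }
    return out


def emit_cohort(config: SimConfig, out_dir: str | Path,
                seed: int | None = None) -> SyntheticTruth:
    """Write the full synthetic cohort to ``out_dir``.

    Produces per-sample ``<sid>.coverage.tsv``, ``<sid>.variants.tsv``
    and ``<sid>.hetsnps.tsv`` plus ``meta.tsv``, ``cytobands.bed``,
    ``cosmic_counts.tsv`` and ``truth.json``.  Output is byte-identical
    across reruns with the same seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth, obs = simulate_cohort(config, seed=seed)
    for sid in sorted(obs["tables"]):
        t = obs["tables"][sid]
        write_coverage_table(t["coverage"], out_dir / f"{sid}.coverage.tsv")
        write_variant_table(t["variants"], out_dir / f"{sid}.variants.tsv")
        write_het_snp_table(t["hetsnps"], out_dir / f"{sid}.hetsnps.tsv")
    write_sample_metadata(sorted(obs["meta"], key=lambda m: m.sample_id),
                          out_dir / "meta.tsv")
    write_cytoband_bed(truth.cytobands, out_dir / "cytobands.bed")
    write_cosmic_table(obs["cosmic"], out_dir / "cosmic_counts.tsv")
    (out_dir / "truth.json").write_text(
        json.dumps(_truth_to_json(truth), sort_keys=True, indent=1) + "\n")
    log.info("wrote synthetic cohort: %d patients, %d samples -> %s",
             len(truth.patients), len(obs["tables"]), out_dir)
    return truth
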