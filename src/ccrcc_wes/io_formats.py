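"""Domain types and tabular/tree I/O shared by every pipeline stage.

All other modules consume and produce the dataclasses defined here.
Coordinate conventions follow each format's native practice: capture
regions and cytobands are BED-style (0-based, half-open), variant
positions are 1-based as in MAF/VCF.  Chromosome names are accepted with
or without a ``chr`` prefix and normalized to the unprefixed dialect.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# chromosome naming and karyotypic order
# ---------------------------------------------------------------------------

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y")
SEX_CHROMOSOMES = frozenset({"X", "Y"})
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


def normalize_chrom(name: str) -> str:
    """Return the unprefixed chromosome name, validating it.

    Accepts ``chr1``/``1`` and ``chrX``/``X`` interchangeably; raises
    :class:`ValueError` on anything outside 1..22, X, Y.
    """
    c = str(name).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c in ("23", "x"):
        c = "X"
    if c in ("24", "y"):
        c = "Y"
    if c not in _CHROM_RANK:
        raise ValueError(f"unknown chromosome name: {name!r}")
    return c


def chrom_rank(name: str) -> int:
    """Karyotypic rank of a chromosome (1..22 then X then Y)."""
    return _CHROM_RANK[normalize_chrom(name)]


def karyotypic_key(chrom: str, start: int = 0, end: int = 0):
    """Sort key giving karyotypic chromosome order, then coordinates."""
    return (chrom_rank(chrom), start, end)


# ---------------------------------------------------------------------------
# effect vocabulary
# ---------------------------------------------------------------------------

EFFECT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel", "splice",
     "synonymous"}
)
INDEL_EFFECTS = frozenset({"frameshift_indel", "inframe_indel"})
NONSYNONYMOUS_EFFECTS = EFFECT_CLASSES - {"synonymous"}

FILTER_REASONS = ("in_normal", "synonymous", "low_reads", "low_corrected_vaf",
                  "none")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaptureRegion:
    """One exome capture interval (BED convention, 0-based half-open)."""

    chrom: str
    start: int
    end: int
    gene: str = ""
    cytoband: str = ""

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not self.start < self.end:
            raise ValueError(
                f"capture region must satisfy start < end, got "
                f"[{self.start}, {self.end}) on chromosome {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def sort_key(self):
        return karyotypic_key(self.chrom, self.start, self.end)


@dataclass
class CoverageRow:
    """Tumor/normal read counts over one capture region."""

    region: CaptureRegion
    tumor_reads: int
    normal_reads: int

    def __post_init__(self):
        if self.tumor_reads < 0 or self.normal_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class VariantCall:
    """One SNV or indel with paired tumor/normal read support."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    effect: str
    tumor_ref_reads: int
    tumor_alt_reads: int
    normal_ref_reads: int
    normal_alt_reads: int
    cosmic_count: int = 0
    vaf_raw: float | None = None
    vaf_corrected: float | None = None
    filter_status: str = "keep"
    rescued_by_cosmic: bool = False

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(
                f"unknown effect class {self.effect!r}; expected one of "
                f"{sorted(EFFECT_CLASSES)}"
            )
        for name in ("tumor_ref_reads", "tumor_alt_reads",
                     "normal_ref_reads", "normal_alt_reads", "cosmic_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.vaf_raw is None:
            d = self.tumor_depth
            self.vaf_raw = self.tumor_alt_reads / d if d > 0 else 0.0

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref_reads + self.tumor_alt_reads

    @property
    def normal_depth(self) -> int:
        return self.normal_ref_reads + self.normal_alt_reads

    @property
    def normal_vaf(self) -> float:
        d = self.normal_depth
        return self.normal_alt_reads / d if d > 0 else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Locus/allele key identifying the same event across samples."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.effect in INDEL_EFFECTS

    @property
    def is_nonsynonymous(self) -> bool:
        return self.effect in NONSYNONYMOUS_EFFECTS

    @property
    def kept(self) -> bool:
        return self.filter_status == "keep"


@dataclass
class HetSNP:
    """A germline-heterozygous SNP with tumor/normal allelic fractions."""

    chrom: str
    pos: int  # 1-based
    tumor_alt_fraction: float
    normal_alt_fraction: float
    tumor_depth: int
    normal_depth: int

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        for f in (self.tumor_alt_fraction, self.normal_alt_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("allelic fractions must lie in [0, 1]")


@dataclass
class SampleMeta:
    """Per-sample metadata linking samples to patients and therapy state."""

    sample_id: str
    patient_id: str
    site: str
    pretreated: bool
    tissue_type: str  # primary | metastasis

    def __post_init__(self):
        if self.tissue_type not in ("primary", "metastasis"):
            raise ValueError(
                f"tissue_type must be 'primary' or 'metastasis', got "
                f"{self.tissue_type!r}"
            )


@dataclass
class Cytoband:
    """One cytogenetic band interval (BED convention)."""

    chrom: str
    start: int
    end: int
    name: str  # full label, e.g. "3p25"

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        if not self.start < self.end:
            raise ValueError("cytoband must satisfy start < end")


@dataclass
class Segment:
    """A contiguous run of capture regions sharing a mean log2 ratio."""

    chrom: str
    start: int
    end: int
    n_regions: int
    seg_mean: float
    call: str = "neutral"
    cytobands: list[str] = field(default_factory=list)
    region_bp: int = 0  # summed capture-region length inside the segment

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return (self.chrom == normalize_chrom(chrom)
                and self.start < end and start < self.end)


# ---------------------------------------------------------------------------
# phylogenetic tree container
# ---------------------------------------------------------------------------

@dataclass
class PhyloNode:
    """Node of a per-patient sample tree; ``length`` is the SNV count of the
    edge joining the node to its parent."""

    name: str
    length: float = 0.0
    children: list["PhyloNode"] = field(default_factory=list)
    snvs: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Per-patient tree over tumor samples rooted at the germline."""

    root: PhyloNode

    def leaves(self) -> list[PhyloNode]:
        out: list[PhyloNode] = []

        def walk(n: PhyloNode):
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def total_length(self) -> float:
        total = 0.0

        def walk(n: PhyloNode):
            nonlocal total
            for c in n.children:
                total += c.length
                walk(c)

        walk(self.root)
        return total

    def clades(self) -> dict[frozenset, float]:
        """Map each non-root clade (the leaf names below an edge) to the
        length of the edge above it."""
        out: dict[frozenset, float] = {}

        def collect(n: PhyloNode) -> frozenset:
            if n.is_leaf:
                below = frozenset({n.name})
            else:
                below = frozenset().union(*(collect(c) for c in n.children))
            out[below] = out.get(below, 0.0) + n.length
            return below

        for c in self.root.children:
            collect(c)
        return out


def format_newick(tree: PhyloTree) -> str:
    """Serialize a :class:`PhyloTree` to a Newick string.

    Branch lengths are SNV counts; the root node carries the label
    ``germline``.  A cycle in the node structure raises ``ValueError``.
    """
    seen: set[int] = set()

    def fmt_len(x: float) -> str:
        return f"{int(x)}" if float(x).is_integer() else f"{x:g}"

    def fmt(node: PhyloNode) -> str:
        if id(node) in seen:
            raise ValueError("cyclic node structure is not a tree")
        seen.add(id(node))
        if node.is_leaf:
            return f"{node.name}:{fmt_len(node.length)}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}):{fmt_len(node.length)}"

    root = tree.root
    if id(root) in seen:  # pragma: no cover - defensive
        raise ValueError("cyclic node structure is not a tree")
    if not root.children:
        raise ValueError("tree has no samples")
    inner = ",".join(fmt(c) for c in root.children)
    return f"({inner}){root.name};"


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(format_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable analysis thresholds with their defaults.

    Variant filtering: a somatic call needs >= ``min_var_reads`` aligned
    tumor reads at the locus and a purity-corrected VAF >= ``min_corrected_vaf``;
    calls failing only the VAF rule can be rescued when reported in COSMIC
    at least ``cosmic_min_reports`` times with corrected tumor VAF >
    ``cosmic_tumor_vaf`` and normal VAF < ``cosmic_normal_vaf``.  Copy
    number: capture regions are dropped by the ``region_min_cov`` rule,
    segments are classified against the ``log2_*`` thresholds, and CBS is
    controlled by ``cbs_alpha``/``cbs_nperm``.
    """

    min_var_reads: int = 10
    min_corrected_vaf: float = 0.10
    cosmic_min_reports: int = 10
    cosmic_tumor_vaf: float = 0.05
    cosmic_normal_vaf: float = 0.01
    normal_presence_vaf: float = 0.02
    normal_presence_min_reads: int = 2
    region_min_cov: int = 100
    region_filter_mode: str = "and"  # exclude when below in both ("and") or either ("or")
    log2_gain: float = 0.5
    log2_amp: float = 1.0
    log2_loss: float = -0.5
    log2_del: float = -1.0
    cbs_alpha: float = 0.01
    cbs_nperm: int = 1000
    cbs_min_width: int = 3
    cbs_merge_delta: float = 0.1
    clonality_presence_threshold: float = 0.25
    purity_min_depth: int = 20
    purity_min_snps: int = 10
    purity_candidate_log2_low: float = -1.0
    purity_candidate_log2_high: float = -0.02
    purity_n_bootstrap: int = 200
    include_sex_chromosomes: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if not (self.log2_del < self.log2_loss < 0 < self.log2_gain
                < self.log2_amp):
            raise ValueError(
                "log2 thresholds must satisfy "
                "log2_del < log2_loss < 0 < log2_gain < log2_amp"
            )
        if self.region_filter_mode not in ("and", "or"):
            raise ValueError("region_filter_mode must be 'and' or 'or'")
        if not 0 < self.cbs_alpha < 1:
            raise ValueError("cbs_alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _open_tsv(path: str | Path, required: Sequence[str]):
    """Yield (line_number, row_dict) for a TSV file, validating the header."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header line")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        for i, row in enumerate(reader, start=2):
            yield i, row


def _parse_int(value: str, what: str, path, line: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValueError(f"{path}: line {line}: {what} is not an integer: "
                         f"{value!r}") from None


def _parse_float(value: str, what: str, path, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"{path}: line {line}: {what} is not a number: "
                         f"{value!r}") from None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

COVERAGE_COLUMNS = ("chrom", "start", "end", "gene", "cytoband",
                    "tumor_reads", "normal_reads")


def read_coverage_table(path: str | Path) -> list[CoverageRow]:
    """Read a per-sample coverage TSV into karyotypically sorted rows.

    Malformed rows raise :class:`ValueError` naming the offending line;
    regions overlapping within a chromosome after sorting are rejected.
    """
    rows: list[CoverageRow] = []
    for line, rec in _open_tsv(path, COVERAGE_COLUMNS):
        try:
            region = CaptureRegion(
                chrom=rec["chrom"],
                start=_parse_int(rec["start"], "start", path, line),
                end=_parse_int(rec["end"], "end", path, line),
                gene=rec.get("gene", "") or "",
                cytoband=rec.get("cytoband", "") or "",
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {line}: {exc}") from None
        rows.append(CoverageRow(
            region=region,
            tumor_reads=_parse_int(rec["tumor_reads"], "tumor_reads", path,
                                   line),
            normal_reads=_parse_int(rec["normal_reads"], "normal_reads", path,
                                    line),
        ))
    rows.sort(key=lambda r: r.region.sort_key)
    prev: CaptureRegion | None = None
    for r in rows:
        if (prev is not None and prev.chrom == r.region.chrom
                and r.region.start < prev.end):
            raise ValueError(
                f"{path}: overlapping capture regions on chromosome "
                f"{prev.chrom}: [{prev.start},{prev.end}) and "
                f"[{r.region.start},{r.region.end})"
            )
        prev = r.region
    log.info("read %d coverage rows from %s", len(rows), path)
    return rows


def write_coverage_table(rows: Iterable[CoverageRow], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(COVERAGE_COLUMNS)
        for r in rows:
            g = r.region
            w.writerow([g.chrom, g.start, g.end, g.gene, g.cytoband,
                        r.tumor_reads, r.normal_reads])


VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "effect",
                   "tumor_ref_reads", "tumor_alt_reads",
                   "normal_ref_reads", "normal_alt_reads")
_VARIANT_OPTIONAL = ("cosmic_count", "vaf_raw", "vaf_corrected",
                     "filter_status", "rescued_by_cosmic")


def read_variant_table(path: str | Path) -> list[VariantCall]:
    """Read a MAF-like variant TSV; ``vaf_raw`` is computed from read
    counts when the column is absent."""
    calls: list[VariantCall] = []
    for line, rec in _open_tsv(path, VARIANT_COLUMNS):
        kwargs = dict(
            chrom=rec["chrom"],
            pos=_parse_int(rec["pos"], "pos", path, line),
            ref=rec["ref"],
            alt=rec["alt"],
            gene=rec.get("gene", "") or "",
            effect=rec["effect"],
            tumor_ref_reads=_parse_int(rec["tumor_ref_reads"],
                                       "tumor_ref_reads", path, line),
            tumor_alt_reads=_parse_int(rec["tumor_alt_reads"],
                                       "tumor_alt_reads", path, line),
            normal_ref_reads=_parse_int(rec["normal_ref_reads"],
                                        "normal_ref_reads", path, line),
            normal_alt_reads=_parse_int(rec["normal_alt_reads"],
                                        "normal_alt_reads", path, line),
        )
        if rec.get("cosmic_count"):
            kwargs["cosmic_count"] = _parse_int(rec["cosmic_count"],
                                                "cosmic_count", path, line)
        if rec.get("vaf_raw"):
            kwargs["vaf_raw"] = _parse_float(rec["vaf_raw"], "vaf_raw", path,
                                             line)
        if rec.get("vaf_corrected"):
            kwargs["vaf_corrected"] = _parse_float(
                rec["vaf_corrected"], "vaf_corrected", path, line)
        if rec.get("filter_status"):
            kwargs["filter_status"] = rec["filter_status"]
        if rec.get("rescued_by_cosmic"):
            kwargs["rescued_by_cosmic"] = rec["rescued_by_cosmic"] == "true"
        try:
            calls.append(VariantCall(**kwargs))
        except ValueError as exc:
            raise ValueError(f"{path}: line {line}: {exc}") from None
    calls.sort(key=lambda v: karyotypic_key(v.chrom, v.pos) + (v.ref, v.alt))
    log.info("read %d variants from %s", len(calls), path)
    return calls


def write_variant_table(calls: Iterable[VariantCall],
                        path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS + _VARIANT_OPTIONAL)
        for v in calls:
            w.writerow([
                v.chrom, v.pos, v.ref, v.alt, v.gene, v.effect,
                v.tumor_ref_reads, v.tumor_alt_reads,
                v.normal_ref_reads, v.normal_alt_reads,
                v.cosmic_count,
                "" if v.vaf_raw is None else f"{v.vaf_raw:.6g}",
                "" if v.vaf_corrected is None else f"{v.vaf_corrected:.6g}",
                v.filter_status,
                "true" if v.rescued_by_cosmic else "false",
            ])


HETSNP_COLUMNS = ("chrom", "pos", "tumor_alt_fraction",
                  "normal_alt_fraction", "tumor_depth", "normal_depth")


def read_het_snp_table(path: str | Path) -> list[HetSNP]:
    snps = []
    for line, rec in _open_tsv(path, HETSNP_COLUMNS):
        try:
            snps.append(HetSNP(
                chrom=rec["chrom"],
                pos=_parse_int(rec["pos"], "pos", path, line),
                tumor_alt_fraction=_parse_float(
                    rec["tumor_alt_fraction"], "tumor_alt_fraction", path,
                    line),
                normal_alt_fraction=_parse_float(
                    rec["normal_alt_fraction"], "normal_alt_fraction", path,
                    line),
                tumor_depth=_parse_int(rec["tumor_depth"], "tumor_depth",
                                       path, line),
                normal_depth=_parse_int(rec["normal_depth"], "normal_depth",
                                        path, line),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}: line {line}: {exc}") from None
    snps.sort(key=lambda s: karyotypic_key(s.chrom, s.pos))
    return snps


def write_het_snp_table(snps: Iterable[HetSNP], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HETSNP_COLUMNS)
        for s in snps:
            w.writerow([s.chrom, s.pos, f"{s.tumor_alt_fraction:.6g}",
                        f"{s.normal_alt_fraction:.6g}", s.tumor_depth,
                        s.normal_depth])


META_COLUMNS = ("sample_id", "patient_id", "site", "pretreated",
                "tissue_type")


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    metas = []
    seen: set[str] = set()
    for line, rec in _open_tsv(path, META_COLUMNS):
        sid = rec["sample_id"]
        if sid in seen:
            raise ValueError(f"{path}: line {line}: duplicate sample_id "
                             f"{sid!r}")
        seen.add(sid)
        flag = rec["pretreated"].strip().lower()
        if flag not in ("true", "false"):
            raise ValueError(f"{path}: line {line}: pretreated must be "
                             f"true/false, got {rec['pretreated']!r}")
        metas.append(SampleMeta(
            sample_id=sid,
            patient_id=rec["patient_id"],
            site=rec["site"],
            pretreated=flag == "true",
            tissue_type=rec["tissue_type"],
        ))
    return metas


def write_sample_metadata(metas: Iterable[SampleMeta],
                          path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(META_COLUMNS)
        for m in metas:
            w.writerow([m.sample_id, m.patient_id, m.site,
                        "true" if m.pretreated else "false", m.tissue_type])


def read_cytoband_bed(path: str | Path) -> list[Cytoband]:
    """Read a 4-column BED of cytobands (chrom, start, end, label)."""
    bands: list[Cytoband] = []
    with Path(path).open() as fh:
        for i, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith(("#", "track")):
                continue
            parts = raw.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {i}: expected 4 BED columns")
            bands.append(Cytoband(
                chrom=parts[0],
                start=_parse_int(parts[1], "start", path, i),
                end=_parse_int(parts[2], "end", path, i),
                name=parts[3],
            ))
    bands.sort(key=lambda b: karyotypic_key(b.chrom, b.start, b.end))
    return bands


def write_cytoband_bed(bands: Iterable[Cytoband], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for b in bands:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.name}\n")


def read_cosmic_table(path: str | Path) -> dict[tuple[str, int, str, str], int]:
    """Read a COSMIC report-count lookup TSV keyed by chrom,pos,ref,alt."""
    counts: dict[tuple[str, int, str, str], int] = {}
    for line, rec in _open_tsv(path, ("chrom", "pos", "ref", "alt", "count")):
        key = (normalize_chrom(rec["chrom"]),
               _parse_int(rec["pos"], "pos", path, line),
               rec["ref"], rec["alt"])
        counts[key] = _parse_int(rec["count"], "count", path, line)
    return counts


def write_cosmic_table(counts: dict[tuple[str, int, str, str], int],
                       path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "pos", "ref", "alt", "count"])
        for key in sorted(counts,
                          key=lambda k: karyotypic_key(k[0], k[1]) + k[2:]):
            w.writerow([key[0], key[1], key[2], key[3], counts[key]])


def annotate_cosmic(calls: Iterable[VariantCall],
                    counts: dict[tuple[str, int, str, str], int]) -> None:
    """Fill ``cosmic_count`` on each call from the lookup (0 when absent)."""
    for v in calls:
        v.cosmic_count = counts.get(v.key, 0)


# SEG: the common 6-column seg_mean dialect
SEG_HEADER = ("ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean")


def write_seg(segments: Iterable[Segment], path: str | Path,
              sample_id: str) -> None:
    """Write segments in SEG format (sample, chrom, start, end, num_mark,
    seg_mean); an empty list produces a header-only file."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SEG_HEADER)
        for s in segments:
            w.writerow([sample_id, s.chrom, s.start, s.end, s.n_regions,
                        f"{s.seg_mean:.6f}"])


def read_seg(path: str | Path) -> list[tuple[str, Segment]]:
    """Read a SEG file back into (sample_id, Segment) pairs.

    Call class and cytoband annotation are not stored in SEG and must be
    recomputed downstream from the segment mean.
    """
    out: list[tuple[str, Segment]] = []
    for line, rec in _open_tsv(path, SEG_HEADER):
        out.append((rec["ID"], Segment(
            chrom=rec["chrom"],
            start=_parse_int(rec["loc.start"], "loc.start", path, line),
            end=_parse_int(rec["loc.end"], "loc.end", path, line),
            n_regions=_parse_int(rec["num.mark"], "num.mark", path, line),
            seg_mean=_parse_float(rec["seg.mean"], "seg.mean", path, line),
        )))
    return out
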