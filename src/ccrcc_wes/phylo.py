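"""Per-patient clonal phylogenies from multi-region SNV presence.

Each patient's filtered SNVs are scored for clonality (cancer cell
fraction) in every sample; a binary presence matrix (SNV x sample,
present when clonality reaches a threshold) is grouped into
sample-presence patterns, and the unique perfect phylogeny over
compatible patterns is assembled rooted at the germline.  Edge lengths
are the SNV counts of their patterns, so the trunk carries the
mutations shared by all samples and leaf edges carry private ones.
Incompatible (overlapping, non-nested) patterns are resolved greedily
by discarding the lowest-count conflicting patterns, with discards
recorded — a deliberately qualitative reconstruction without bootstrap
support.

A variant falling in a homozygously deleted segment in some sample
cannot be observed there; such loci are treated as missing data and
excluded from tree building rather than scored as absent.  The mask
keys on deep-deletion scale (segment mean below log2(0.25), i.e. under
half a copy) rather than the five-class "deletion" label, because a
hemizygous loss in a pure tumor sits exactly at the -1 call boundary
and still yields reads from its remaining copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PhyloNode, PhyloTree, Segment, VariantCall
from .snv import infer_multiplicity, local_copy_number

log = logging.getLogger(__name__)

CLONALITY_FLAG_LIMIT = 1.2  # above this the admixture model is suspect
DEEP_DELETION_LOG2 = -2.0  # below ~half a copy the locus is unobservable


def compute_clonality(vaf_raw: float, purity: float, local_cn: int,
                      multiplicity: int = 1) -> float:
    """Cancer cell fraction estimate for one variant in one sample.

    clonality = VAF_raw * (p*CN + 2*(1-p)) / (p * multiplicity).
    Reported uncapped; values above ~1.2 indicate a model violation
    (wrong CN/multiplicity or purity) and are flagged by callers.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    if local_cn < 0:
        raise ValueError("local copy number must be non-negative")
    return vaf_raw * (purity * local_cn + 2.0 * (1.0 - purity)) / (
        purity * multiplicity)


@dataclass
class PresenceMatrix:
    """Clonality-thresholded SNV presence across a patient's samples."""

    presence: pd.DataFrame  # bool, index variant key, columns sample ids
    clonality: pd.DataFrame  # float, same shape
    n_missing_dropped: int = 0  # variants excluded as missing data
    variant_genes: dict = field(default_factory=dict)


def build_presence_matrix(calls_by_sample: Mapping[str, Sequence[VariantCall]],
                          purity_by_sample: Mapping[str, float],
                          segments_by_sample: Mapping[str, Sequence[Segment]],
                          threshold: float = 0.25) -> PresenceMatrix:
    """Binary SNV-by-sample presence from per-sample clonality.

    A variant is *present* in a sample when its clonality reaches
    ``threshold`` there; variants must have passed the somatic filters
    in at least one sample, and rows absent everywhere are dropped.
    Requires >= 2 samples.
    """
    samples = sorted(calls_by_sample)
    if len(samples) < 2:
        raise ValueError(
            "phylogeny needs >= 2 samples for a patient; skip this patient")
    by_key: dict[str, dict[str, VariantCall]] = {}
    genes: dict[str, str] = {}
    for sid in samples:
        for call in calls_by_sample[sid]:
            key = "{}:{}:{}:{}".format(*call.key)
            by_key.setdefault(key, {})[sid] = call
            genes.setdefault(key, call.gene)
    keys = sorted(by_key)
    clon = np.zeros((len(keys), len(samples)))
    missing = np.zeros_like(clon, dtype=bool)
    passed = np.zeros(len(keys), dtype=bool)
    for ki, key in enumerate(keys):
        for si, sid in enumerate(samples):
            call = by_key[key].get(sid)
            if call is None:
                continue
            segs = segments_by_sample.get(sid) or []
            hit = next((s for s in segs
                        if s.overlaps(call.chrom, call.pos - 1, call.pos)),
                       None)
            if hit is not None and hit.seg_mean < DEEP_DELETION_LOG2:
                missing[ki, si] = True
                continue
            p = purity_by_sample[sid]
            cn = local_copy_number(call, segs)
            mult = infer_multiplicity(call, p, cn)
            c = compute_clonality(call.vaf_raw, p, cn, mult)
            if c > CLONALITY_FLAG_LIMIT:
                log.debug("clonality %.2f > %.1f at %s in %s "
                          "(model violation)", c, CLONALITY_FLAG_LIMIT,
                          key, sid)
            clon[ki, si] = c
            if call.kept:
                passed[ki] = True
    presence = (clon >= threshold) & ~missing
    any_missing = missing.any(axis=1)
    n_missing = int((any_missing & passed).sum())
    keep_rows = passed & presence.any(axis=1) & ~any_missing
    if n_missing:
        log.info("excluded %d variants with deletion-masked loci as "
                 "missing data", n_missing)
    idx = pd.Index(keys, name="variant")
    presence_df = pd.DataFrame(presence, index=idx, columns=samples)
    clon_df = pd.DataFrame(clon, index=idx, columns=samples)
    return PresenceMatrix(
        presence=presence_df.loc[keep_rows],
        clonality=clon_df.loc[keep_rows],
        n_missing_dropped=n_missing,
        variant_genes={k: genes[k] for k, keep in zip(keys, keep_rows)
                       if keep},
    )


# ---------------------------------------------------------------------------
# perfect phylogeny assembly
# ---------------------------------------------------------------------------

def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


@dataclass
class TreeBuildResult:
    tree: PhyloTree
    discarded_patterns: list[tuple[frozenset, int]]
    n_snvs_used: int


def build_tree(matrix: PresenceMatrix) -> TreeBuildResult:
    """Assemble the perfect phylogeny over sample-presence patterns.

    SNVs sharing a presence pattern form one edge with length equal to
    the pattern's SNV count.  When two patterns overlap without
    nesting, the one with fewer SNVs is discarded (ties broken
    deterministically) until the family is laminar; discards are
    returned.  The root is the germline (no mutations); every sample is
    a leaf, with a zero-length edge when it has no private SNVs.
    """
    presence = matrix.presence
    if presence.empty:
        raise ValueError("presence matrix is empty; nothing to build")
    samples = list(presence.columns)
    patterns: dict[frozenset, list] = {}
    for key, row in presence.iterrows():
        clade = frozenset(s for s in samples if row[s])
        patterns.setdefault(clade, []).append(key)
    ordered = sorted(patterns.items(),
                     key=lambda kv: (-len(kv[1]), -len(kv[0]),
                                     tuple(sorted(kv[0]))))
    kept: list[frozenset] = []
    discarded: list[tuple[frozenset, int]] = []
    for clade, keys in ordered:
        if all(_compatible(clade, other) for other in kept):
            kept.append(clade)
        else:
            discarded.append((clade, len(keys)))
    if discarded:
        log.info("discarded %d conflicting presence patterns (%d SNVs)",
                 len(discarded), sum(n for _, n in discarded))
    node_for: dict[frozenset, PhyloNode] = {}
    root = PhyloNode(name="germline")
    # internal nodes for non-singleton patterns, largest first
    internals = sorted((c for c in kept if len(c) > 1),
                       key=lambda c: (-len(c), tuple(sorted(c))))
    for clade in internals:
        node = PhyloNode(name="", length=len(patterns[clade]),
                         snvs=sorted(patterns[clade]))
        parent = root
        best: frozenset | None = None
        for other in internals:
            if other != clade and clade < other:
                if best is None or len(other) < len(best):
                    best = other
        if best is not None:
            parent = node_for[best]
        parent.children.append(node)
        node_for[clade] = node
    for sid in samples:
        singleton = frozenset({sid})
        n_private = len(patterns.get(singleton, [])) \
            if singleton in kept else 0
        leaf = PhyloNode(name=sid, length=n_private,
                         snvs=sorted(patterns.get(singleton, []))
                         if singleton in kept else [])
        best = None
        for clade in internals:
            if sid in clade and (best is None or len(clade) < len(best)):
                best = clade
        (node_for[best] if best is not None else root).children.append(leaf)
    # deterministic child order: by the sorted leaf names below each child
    def sort_children(n: PhyloNode):
        n.children.sort(key=lambda c: tuple(sorted(_leafset(c))))
        for c in n.children:
            sort_children(c)

    def _leafset(n: PhyloNode) -> set:
        if n.is_leaf:
            return {n.name}
        out: set = set()
        for c in n.children:
            out |= _leafset(c)
        return out

    sort_children(root)
    n_used = sum(len(patterns[c]) for c in kept)
    return TreeBuildResult(tree=PhyloTree(root=root),
                           discarded_patterns=discarded,
                           n_snvs_used=n_used)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def tree_metrics(tree: PhyloTree) -> dict:
    """Truncal fraction, depth and branching count for one tree.

    The truncal edge is the edge below the germline whose clade holds
    every sample; a star tree has truncal fraction 1.0 when all SNVs are
    shared (0.0 when there is no truncal edge).
    """
    leaves = {leaf.name for leaf in tree.leaves()}
    clades = tree.clades()
    total = tree.total_length()
    truncal = clades.get(frozenset(leaves), 0.0)

    def depth(n: PhyloNode) -> int:
        if n.is_leaf:
            return 0
        return 1 + max(depth(c) for c in n.children)

    n_branching = 0

    def count(n: PhyloNode):
        nonlocal n_branching
        if len(n.children) >= 2:
            n_branching += 1
        for c in n.children:
            count(c)

    count(tree.root)
    return {
        "truncal_fraction": truncal / total if total else 0.0,
        "max_depth": depth(tree.root),
        "n_branching_nodes": n_branching,
        "total_snvs": total,
        "n_samples": len(leaves),
    }
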