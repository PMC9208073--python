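"""Cohort-level aggregation and therapy-naive vs pretreated contrasts.

Gene mutation frequencies are patient-level proportions (a patient
counts once per gene however many of their samples carry it).  Group
contrasts — per-gene corrected VAF, TMB, indel fraction and CNA burden
between therapy-naive and pretreated samples — use the two-sided
Mann-Whitney-Wilcoxon test with Benjamini-Hochberg FDR correction
applied across the per-gene VAF family.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleMeta, VariantCall

log = logging.getLogger(__name__)


def gene_frequencies(kept_calls_by_sample: Mapping[str, Sequence[VariantCall]],
                     meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Patient-level mutation frequency per gene, with effect breakdown.

    Sorted by frequency descending, ties alphabetical.  Only calls with
    status ``keep`` contribute; the denominator is the number of
    patients in the metadata.
    """
    if not meta:
        raise ValueError("empty sample metadata")
    patient_of = {m.sample_id: m.patient_id for m in meta}
    n_patients = len({m.patient_id for m in meta})
    mutated: dict[str, set[str]] = {}
    effects: dict[str, dict[str, set[str]]] = {}
    for sid, calls in kept_calls_by_sample.items():
        pid = patient_of.get(sid)
        if pid is None:
            raise ValueError(f"sample {sid!r} missing from metadata")
        for c in calls:
            if not c.kept or not c.gene:
                continue
            mutated.setdefault(c.gene, set()).add(pid)
            effects.setdefault(c.gene, {}).setdefault(c.effect, set()) \
                .add(pid)
    rows = []
    for gene in mutated:
        n_mut = len(mutated[gene])
        row = {
            "gene": gene,
            "n_mutated_patients": n_mut,
            "n_patients": n_patients,
            "frequency": n_mut / n_patients,
        }
        for eff, pids in effects[gene].items():
            row[f"n_{eff}"] = len(pids)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["gene", "n_mutated_patients",
                                     "n_patients", "frequency"])
    df = df.sort_values(["frequency", "gene"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    return df.fillna(0)


def mann_whitney_u(values_a: Sequence[float], values_b: Sequence[float],
                   ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the smaller group has <= 8
    observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Returns
    (U of the first group, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = min(a.size, b.size) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1.

    Order-equivariant: permuting the input permutes the output the same
    way.  NaNs pass through untouched.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _groups(meta: Sequence[SampleMeta]) -> tuple[list[str], list[str]]:
    naive = sorted(m.sample_id for m in meta if not m.pretreated)
    pre = sorted(m.sample_id for m in meta if m.pretreated)
    return naive, pre


def compare_by_treatment(kept_calls_by_sample: Mapping[str, Sequence[VariantCall]],
                         tmb_by_sample: Mapping[str, float],
                         indel_fraction_by_sample: Mapping[str, float],
                         burden_by_sample: Mapping[str, float],
                         meta: Sequence[SampleMeta],
                         genes: Sequence[str] | None = None,
                         min_gene_samples: int = 5) -> pd.DataFrame:
    """Therapy-naive vs pretreated contrasts, one row per metric.

    Per-gene rows compare the corrected VAF of that gene's kept
    mutations between samples in each group (per-mutation pooling);
    TMB, indel fraction and CNA burden compare sample-level values.
    BH correction is applied within the per-gene VAF family; metrics
    with fewer than two observations in a group report p = NaN with a
    warning.  By default the family covers recurrently mutated genes
    (>= ``min_gene_samples`` kept calls cohort-wide).
    """
    naive_ids, pre_ids = _groups(meta)
    if genes is None:
        seen: dict[str, int] = {}
        for calls in kept_calls_by_sample.values():
            for c in calls:
                if c.kept and c.gene:
                    seen[c.gene] = seen.get(c.gene, 0) + 1
        genes = sorted(g for g, n in seen.items() if n >= min_gene_samples)

    def gene_vafs(ids: list[str], gene: str) -> list[float]:
        out = []
        for sid in ids:
            for c in kept_calls_by_sample.get(sid, []):
                if c.kept and c.gene == gene and c.vaf_corrected is not None:
                    out.append(c.vaf_corrected)
        return out

    rows = []
    for gene in genes:
        va, vb = gene_vafs(naive_ids, gene), gene_vafs(pre_ids, gene)
        rows.append(_contrast_row(f"VAF:{gene}", va, vb, family="vaf"))
    for name, table in (("TMB", tmb_by_sample),
                        ("indel_fraction", indel_fraction_by_sample),
                        ("cna_burden", burden_by_sample)):
        va = [table[s] for s in naive_ids if s in table]
        vb = [table[s] for s in pre_ids if s in table]
        rows.append(_contrast_row(name, va, vb, family="global"))
    df = pd.DataFrame(rows)
    df["q_value"] = np.nan
    vaf_mask = df["family"] == "vaf"
    df.loc[vaf_mask, "q_value"] = adjust_bh(df.loc[vaf_mask, "p_value"])
    # single-metric rows carry their raw p as q (family of size one each)
    df.loc[~vaf_mask, "q_value"] = df.loc[~vaf_mask, "p_value"]
    return df.drop(columns=["family"])


def _contrast_row(metric: str, va: list[float], vb: list[float],
                  family: str) -> dict:
    row = {
        "metric": metric,
        "group_a": "naive",
        "group_b": "pretreated",
        "n_a": len(va),
        "n_b": len(vb),
        "median_a": float(np.median(va)) if va else np.nan,
        "median_b": float(np.median(vb)) if vb else np.nan,
        "U": np.nan,
        "p_value": np.nan,
        "family": family,
    }
    if len(va) < 2 or len(vb) < 2:
        log.warning("metric %s: fewer than 2 observations in a group "
                    "(n=%d vs %d); p set to NA", metric, len(va), len(vb))
        return row
    u, p = mann_whitney_u(va, vb)
    row["U"] = u
    row["p_value"] = p
    return row
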