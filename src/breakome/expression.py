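"""Association between TSS-proximal hotspots and gene expression.

Per tissue, genes with vs without a hotspot within +/-200 bp of any of
their TSSs are compared on log2(TPM + 1) with a two-sided Wilcoxon
rank-sum test. Pooled across tissues, genes are classified
hierarchically into the six distance bins per strand (most proximal bin
wins within a tissue and strand) and bin groups compared pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hotspots import HotspotSet
from .io_core import ExpressionMatrix, TssTable
from .tss_enrichment import BIN_LABELS, TssIndex, assign_to_tss, bin_of

logger = logging.getLogger(__name__)

__all__ = ["ExpressionComparison", "representative_transcript", "tissue_expression",
           "gene_hotspot_status", "with_without_comparison", "hierarchical_bins",
           "rank_sum_test"]

STRAND_CLASSES = ("template", "nontemplate")


@dataclass
class ExpressionComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    median_a: float      # median log2(TPM+1)
    median_b: float
    p_value: float
    testable: bool = True


def representative_transcript(tss_table: TssTable, rng_seed: int = 0) -> pd.DataFrame:
    """Choose one transcript per gene uniformly at random (seeded).

    Returns the chosen TSS rows, one per gene, sorted by gene_id.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for gene_id, grp in tss_table.df.sort_values(
            ["gene_id", "transcript_id"]).groupby("gene_id", sort=True):
        rows.append(grp.iloc[rng.integers(len(grp))])
    return pd.DataFrame(rows).reset_index(drop=True)


def tissue_expression(expr: ExpressionMatrix, tissue: str) -> pd.Series:
    """Mean TPM per gene over the tissue's samples."""
    samples = expr.tissue_samples(tissue)
    if not samples:
        raise ValueError(f"unknown tissue {tissue!r}")
    return expr.tpm[samples].mean(axis=1)


def _log2p1(x) -> np.ndarray:
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def rank_sum_test(values_a, values_b, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney U) p-value, exact when possible."""
    return float(stats.mannwhitneyu(values_a, values_b,
                                    alternative=alternative).pvalue)


def gene_hotspot_status(hotspots: HotspotSet, tss_table: TssTable,
                        max_distance: int = 200) -> pd.DataFrame:
    """Per-gene, per-strand hotspot presence and most-proximal distance bin.

    A gene counts as hotspot-bearing when any of its annotated TSSs has
    a hotspot within ``max_distance``; hotspots are attributed to genes
    through nearest-TSS assignment. Returns one row per gene present in
    the TSS table with boolean template/nontemplate flags and the most
    proximal bin label per strand ("none" when absent).
    """
    index = TssIndex(tss_table)
    assignments = assign_to_tss(hotspots.positions, index, max_distance=max_distance)
    genes = tss_table.genes()
    status = pd.DataFrame({"gene_id": genes}).set_index("gene_id")
    for cls in STRAND_CLASSES:
        status[f"has_{cls}"] = False
        status[f"bin_{cls}"] = "none"
    if len(assignments):
        assignments = assignments.copy()
        assignments["bin_idx"] = bin_of(assignments["abs_distance"].values)
        for cls in STRAND_CLASSES:
            sub = assignments[assignments["strand_class"] == cls]
            best = sub.groupby("gene_id")["bin_idx"].min()
            present = best.index.intersection(status.index)
            status.loc[present, f"has_{cls}"] = True
            status.loc[present, f"bin_{cls}"] = [BIN_LABELS[i] for i in best.loc[present]]
    return status.reset_index()


def with_without_comparison(status: pd.DataFrame, expr: ExpressionMatrix,
                            tissue: str, strand_scope: str = "either") -> ExpressionComparison:
    """Expression of hotspot-bearing vs hotspot-free genes in one tissue.

    ``strand_scope``: "either", "template" or "nontemplate".
    """
    if strand_scope == "either":
        has = status["has_template"] | status["has_nontemplate"]
    elif strand_scope in STRAND_CLASSES:
        has = status[f"has_{strand_scope}"]
    else:
        raise ValueError(f"unknown strand_scope {strand_scope!r}")
    tpm = tissue_expression(expr, tissue)
    genes = status["gene_id"]
    common = genes[genes.isin(tpm.index)]
    has = has[genes.isin(tpm.index)].values
    vals = _log2p1(tpm.loc[common].values)
    a, b = vals[has], vals[~has]
    if len(a) == 0 or len(b) == 0:
        return ExpressionComparison("with_hotspot", "without_hotspot", len(a), len(b),
                                    float("nan"), float("nan"), float("nan"),
                                    testable=False)
    return ExpressionComparison("with_hotspot", "without_hotspot", len(a), len(b),
                                float(np.median(a)), float(np.median(b)),
                                rank_sum_test(a, b))


def hierarchical_bins(statuses: dict[str, pd.DataFrame], expr: ExpressionMatrix,
                      pooling: str = "union") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled distance-bin gene groups and their pairwise rank-sum tests.

    ``statuses`` maps tissue -> per-gene status frame (from
    :func:`gene_hotspot_status` on that tissue's hotspots). A gene joins
    the (bin, strand) group of every tissue in which that bin is its
    most proximal on that strand (``pooling="union"``, matching the
    pooled-cohort rule) or only its single most proximal bin across
    tissues (``pooling="most_proximal"``). Expression contributed is the
    gene's mean TPM in the qualifying tissue, displayed as log2(TPM+1).

    Returns (membership frame, pairwise test frame).
    """
    if pooling not in ("union", "most_proximal"):
        raise ValueError(f"unknown pooling {pooling!r}")
    rows = []
    for tissue, status in statuses.items():
        tpm = tissue_expression(expr, tissue)
        for cls in STRAND_CLASSES:
            sub = status[status[f"bin_{cls}"] != "none"]
            for gene, bin_label in zip(sub["gene_id"], sub[f"bin_{cls}"]):
                if gene not in tpm.index:
                    continue
                rows.append({"gene_id": gene, "tissue": tissue, "strand": cls,
                             "bin": bin_label,
                             "log2_tpm1": float(_log2p1(tpm.loc[gene]))})
    members = pd.DataFrame(rows, columns=["gene_id", "tissue", "strand", "bin",
                                          "log2_tpm1"])
    if pooling == "most_proximal" and len(members):
        order = {lbl: i for i, lbl in enumerate(BIN_LABELS)}
        members["_o"] = members["bin"].map(order)
        best = members.groupby(["gene_id", "strand"])["_o"].transform("min")
        members = members[members["_o"] == best].drop(columns="_o")
    tests = []
    for cls in STRAND_CLASSES:
        sub = members[members["strand"] == cls]
        groups = {lbl: sub[sub["bin"] == lbl]["log2_tpm1"].values for lbl in BIN_LABELS}
        for i, la in enumerate(BIN_LABELS):
            for lb in BIN_LABELS[i + 1:]:
                a, b = groups[la], groups[lb]
                if len(a) == 0 or len(b) == 0:
                    logger.warning("empty group %s/%s or %s/%s; test skipped",
                                   cls, la, cls, lb)
                    continue
                tests.append({"strand": cls, "bin_a": la, "bin_b": lb,
                              "n_a": len(a), "n_b": len(b),
                              "median_a": float(np.median(a)),
                              "median_b": float(np.median(b)),
                              "p_value": rank_sum_test(a, b)})
    return members, pd.DataFrame(tests, columns=["strand", "bin_a", "bin_b", "n_a",
                                                 "n_b", "median_a", "median_b",
                                                 "p_value"])
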