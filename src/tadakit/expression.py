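"""Integration of DamID binding with differential expression and tissue data.

Consumes a differential-expression results table (gene_id, log2 fold
change, adjusted p — as produced by any standard DE fitter), applies
the significance thresholds (padj < 0.05 and |log2FC| > 1, both
strict), tests bound-gene / DE-gene overlap with a one-sided Fisher's
exact test, and classifies genes by tissue of origin from a
gene x tissue FPKM matrix using the FPKM > 2 non-background rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DETable",
    "ExpressionMatrix",
    "OverlapResult",
    "BoundDEReport",
    "TissueReport",
    "classify_de",
    "overlap_test",
    "tissue_of_origin",
    "bound_de_overlap_report",
    "read_de_table",
    "read_fpkm_matrix",
    "DEFAULT_PADJ_CUTOFF",
    "DEFAULT_LFC_CUTOFF",
    "DEFAULT_FPKM_THRESHOLD",
]

DEFAULT_PADJ_CUTOFF = 0.05
DEFAULT_LFC_CUTOFF = 1.0
DEFAULT_FPKM_THRESHOLD = 2.0


@dataclass
class DETable:
    """DE results: one row per gene (gene_id, log2_fold_change, adjusted_p)."""

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"gene_id", "log2_fold_change", "adjusted_p"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        if self.frame["gene_id"].duplicated().any():
            dup = self.frame["gene_id"][self.frame["gene_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate gene_id in DE table: {dup!r}")
        p = self.frame["adjusted_p"]
        bad = p.notna() & ((p < 0) | (p > 1))
        if bad.any():
            raise ValueError("adjusted_p values must lie in [0, 1]")


@dataclass
class ExpressionMatrix:
    """Gene x tissue FPKM matrix with one focal tissue (e.g. the CNS)."""

    frame: pd.DataFrame  # index: gene_id, columns: tissue names
    focal_tissue: str

    def __post_init__(self):
        if self.frame.shape[1] == 0:
            raise ValueError("expression matrix has no tissues")
        if self.focal_tissue not in self.frame.columns:
            raise ValueError(f"focal tissue {self.focal_tissue!r} not in matrix")
        if (self.frame.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")


@dataclass
class OverlapResult:
    """2x2 overlap of two gene sets within a universe.

    ``p_value`` is the one-sided (enrichment) Fisher's exact p, i.e.
    the hypergeometric tail P(X >= |A intersect B|); ``odds_ratio`` is
    the sample odds ratio, reported as inf when a zero cell makes the
    denominator vanish.
    """

    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    odds_ratio: float
    p_value: float

    @property
    def universe_size(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only + self.n_neither


@dataclass
class BoundDEReport:
    up: OverlapResult
    down: OverlapResult
    up_bound_fraction: float
    down_bound_fraction: float


@dataclass
class TissueReport:
    labels: dict[str, str]  # gene -> label
    fractions: dict[str, float]  # label -> fraction of labelled genes
    absent: list[str]  # genes not present in the matrix


def classify_de(
    table: DETable,
    padj_cutoff: float = DEFAULT_PADJ_CUTOFF,
    lfc_cutoff: float = DEFAULT_LFC_CUTOFF,
) -> tuple[set[str], set[str]]:
    """(upregulated, downregulated) gene sets under strict thresholds.

    up: padj < cutoff AND lfc > lfc_cutoff; down: padj < cutoff AND
    lfc < -lfc_cutoff.  Genes at exactly a cutoff are not significant;
    rows with missing adjusted p are excluded.
    """
    if padj_cutoff <= 0 or lfc_cutoff <= 0:
        raise ValueError("thresholds must be positive")
    df = table.frame
    ok = df["adjusted_p"].notna() & (df["adjusted_p"] < padj_cutoff)
    up = set(df.loc[ok & (df["log2_fold_change"] > lfc_cutoff), "gene_id"])
    down = set(df.loc[ok & (df["log2_fold_change"] < -lfc_cutoff), "gene_id"])
    return up, down


def overlap_test(set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]) -> OverlapResult:
    """One-sided Fisher's exact enrichment test of two sets in a universe."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if len(u) < 1:
        raise ValueError("universe must be non-empty")
    if not a <= u:
        raise ValueError("set_a is not a subset of the universe")
    if not b <= u:
        raise ValueError("set_b is not a subset of the universe")
    k = len(a & b)
    n_a_only = len(a) - k
    n_b_only = len(b) - k
    n_neither = len(u) - len(a | b)
    # P(X >= k), X ~ Hypergeom(M=|U|, n=|A|, N=|B|)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    num = k * n_neither
    den = n_a_only * n_b_only
    odds = math.inf if den == 0 else num / den
    return OverlapResult(k, n_a_only, n_b_only, n_neither, odds, min(p, 1.0))


def tissue_of_origin(
    genes: Iterable[str],
    matrix: ExpressionMatrix,
    fpkm_threshold: float = DEFAULT_FPKM_THRESHOLD,
) -> TissueReport:
    """Label genes by tissue of origin under the FPKM > threshold rule.

    focal-tissue when the focal FPKM exceeds the threshold; otherwise
    non-focal:<argmax tissue> when any tissue exceeds it (ties broken
    by lexicographic tissue name); otherwise not-detected.  FPKM equal
    to the threshold counts as background.  Genes absent from the
    matrix are reported separately, never silently dropped.
    """
    df = matrix.frame
    tissues = sorted(df.columns)  # lexicographic order fixes argmax ties
    labels: dict[str, str] = {}
    absent: list[str] = []
    for gene in genes:
        if gene not in df.index:
            absent.append(gene)
            continue
        row = df.loc[gene]
        if row[matrix.focal_tissue] > fpkm_threshold:
            labels[gene] = "focal-tissue"
            continue
        best_tissue, best = None, fpkm_threshold
        for t in tissues:
            if row[t] > best:
                best_tissue, best = t, row[t]
        labels[gene] = f"non-focal:{best_tissue}" if best_tissue else "not-detected"
    n = len(labels)
    fractions: dict[str, float] = {}
    for lab in labels.values():
        fractions[lab] = fractions.get(lab, 0.0) + (1.0 / n if n else 0.0)
    return TissueReport(labels, fractions, absent)


def bound_de_overlap_report(
    bound_genes: Iterable[str],
    up: Iterable[str],
    down: Iterable[str],
    universe: Iterable[str],
) -> BoundDEReport:
    """Enrichment of bound genes among up/down DE genes + bound fractions."""
    bound, up, down = set(bound_genes), set(up), set(down)
    up_res = overlap_test(up, bound, universe)
    down_res = overlap_test(down, bound, universe)
    up_frac = len(up & bound) / len(up) if up else math.nan
    down_frac = len(down & bound) / len(down) if down else math.nan
    return BoundDEReport(up_res, down_res, up_frac, down_frac)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_de_table(source) -> DETable:
    """Tab-delimited DE results with header (gene_id, log2_fold_change, adjusted_p)."""
    df = pd.read_csv(source, sep="\t", comment="#")
    return DETable(df[["gene_id", "log2_fold_change", "adjusted_p"]])


def read_fpkm_matrix(source, focal_tissue: str) -> ExpressionMatrix:
    """Tab-delimited gene x tissue FPKM matrix; first column = gene_id."""
    df = pd.read_csv(source, sep="\t", comment="#", index_col=0)
    return ExpressionMatrix(df, focal_tissue)


def overlap_report_text(report: BoundDEReport) -> str:
    lines = ["direction\tn_de\tn_bound_de\tbound_fraction\todds_ratio\tp_value"]
    for name, res, frac in (
        ("up", report.up, report.up_bound_fraction),
        ("down", report.down, report.down_bound_fraction),
    ):
        n_de = res.n_both + res.n_a_only
        lines.append(
            f"{name}\t{n_de}\t{res.n_both}\t{format(frac, '.4g')}\t"
            f"{format(res.odds_ratio, '.4g')}\t{format(res.p_value, '.4g')}"
        )
    return "\n".join(lines) + "\n"
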