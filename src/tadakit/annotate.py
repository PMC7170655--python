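"""Peak-to-gene assignment and genomic-feature classification.

A gene is considered potentially regulated by a peak when it overlaps
the peak, or lies within ``max_distance`` (default 5 kb) of it with no
other gene lying entirely inside the intervening gap.  Distances are
edge-to-edge.  Strand does not affect assignment; it only matters for
the promoter/TTS windows of the feature classifier.

The feature classifier assigns each peak, by midpoint, to exactly one
of promoter-TSS / TTS / exon / intron / intergenic with that priority
order (a midpoint in both a promoter window and an exon counts as
promoter-TSS).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel
from .peaks import Peak, PeakSet

__all__ = [
    "GeneAssignment",
    "FeatureBreakdown",
    "assign_genes",
    "classify_features",
    "venn_counts",
    "FEATURE_CATEGORIES",
    "DEFAULT_MAX_DISTANCE",
    "DEFAULT_PROMOTER_WINDOW",
    "DEFAULT_TTS_WINDOW",
]

DEFAULT_MAX_DISTANCE = 5000
DEFAULT_PROMOTER_WINDOW = (1000, 100)  # upstream, downstream of TSS, bp
DEFAULT_TTS_WINDOW = 100  # +/- bp around TTS

FEATURE_CATEGORIES = ("promoter-TSS", "TTS", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class GeneAssignment:
    peak_id: str
    gene_id: str
    distance: int  # bp, 0 when peak and gene span overlap


@dataclass
class FeatureBreakdown:
    counts: dict[str, int]
    fractions: dict[str, float]
    total: int


def _gap(peak: Peak, gene: GeneModel) -> int:
    """Edge-to-edge distance; 0 when the spans overlap."""
    if gene.start >= peak.end:
        return gene.start - peak.end
    if gene.end <= peak.start:
        return peak.start - gene.end
    return 0


def assign_genes(
    peaks: PeakSet | Sequence[Peak],
    genes: Sequence[GeneModel],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> list[GeneAssignment]:
    """All (peak, gene) pairs under the 5 kb / no-intervening-gene rule.

    A gene qualifies iff it overlaps the peak, or the edge-to-edge gap
    is <= max_distance and no *other* gene's span lies entirely within
    that gap.  A gene partially overlapping the gap (e.g. one that also
    overlaps the peak) does not block.  One peak may yield several
    genes and one gene several peaks; pairs are unique.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be non-negative")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for v in by_chrom.values():
        v.sort(key=lambda g: (g.start, g.end))

    out: list[GeneAssignment] = []
    seen: set[tuple[str, str]] = set()
    peak_list = list(peaks)
    for idx, peak in enumerate(peak_list, 1):
        pid = f"peak_{idx}"
        chrom_genes = by_chrom.get(peak.chrom, [])
        for gene in chrom_genes:
            gap = _gap(peak, gene)
            if gap > max_distance:
                continue
            if gap > 0:
                # open gap between the facing edges
                if gene.start >= peak.end:
                    lo, hi = peak.end, gene.start
                else:
                    lo, hi = gene.end, peak.start
                blocked = any(
                    other is not gene and other.start >= lo and other.end <= hi
                    for other in chrom_genes
                )
                if blocked:
                    continue
            key = (pid, gene.gene_id)
            if key not in seen:
                seen.add(key)
                out.append(GeneAssignment(pid, gene.gene_id, gap))
    return out


def _classify_midpoint(
    mid: int,
    chrom: str,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int],
    tts_window: int,
) -> str:
    upstream, downstream = promoter_window
    in_promoter = in_tts = in_exon = in_gene = False
    for g in genes:
        if g.chrom != chrom:
            continue
        rel = mid - g.tss if g.strand == "+" else g.tss - mid
        if -upstream <= rel <= downstream:
            in_promoter = True
        if abs(mid - g.tts) <= tts_window:
            in_tts = True
        if g.start <= mid < g.end:
            in_gene = True
            exons = g.exons if g.exons else ((g.start, g.end),)
            if any(s <= mid < e for s, e in exons):
                in_exon = True
    if in_promoter:
        return "promoter-TSS"
    if in_tts:
        return "TTS"
    if in_exon:
        return "exon"
    if in_gene:
        return "intron"
    return "intergenic"


def classify_features(
    peaks: PeakSet | Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    tts_window: int = DEFAULT_TTS_WINDOW,
) -> FeatureBreakdown:
    """Classify each peak midpoint into exactly one feature category.

    Genes without annotated exons are treated as single-exon.
    """
    peak_list = list(peaks)
    counts = {c: 0 for c in FEATURE_CATEGORIES}
    for p in peak_list:
        mid = (p.start + p.end) // 2
        counts[_classify_midpoint(mid, p.chrom, genes, promoter_window, tts_window)] += 1
    total = len(peak_list)
    fractions = {c: (counts[c] / total if total else 0.0) for c in FEATURE_CATEGORIES}
    return FeatureBreakdown(counts, fractions, total)


def venn_counts(gene_sets: Mapping[str, Iterable[str]]) -> dict[frozenset, int]:
    """Exact element counts of every non-empty membership pattern.

    Keys are frozensets of set names; value for key K = number of
    elements belonging to exactly the sets in K.  All 2^k - 1 patterns
    are present (zeros included); their counts sum to |union|.
    """
    names = list(gene_sets)
    if len(names) < 2:
        raise ValueError("venn_counts needs at least 2 named sets")
    if len(names) > 6:
        raise ValueError(f"venn_counts supports at most 6 sets, got {len(names)}")
    sets = {n: set(gene_sets[n]) for n in names}
    out: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            out[frozenset(combo)] = 0
    union = set().union(*sets.values())
    for el in union:
        pattern = frozenset(n for n in names if el in sets[n])
        out[pattern] += 1
    return out


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def assignments_to_frame(assignments: Sequence[GeneAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [a.peak_id for a in assignments],
            "gene_id": [a.gene_id for a in assignments],
            "distance": [a.distance for a in assignments],
        }
    )


def breakdown_to_frame(b: FeatureBreakdown) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": list(FEATURE_CATEGORIES),
            "count": [b.counts[c] for c in FEATURE_CATEGORIES],
            "fraction": [b.fractions[c] for c in FEATURE_CATEGORIES],
        }
    )
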