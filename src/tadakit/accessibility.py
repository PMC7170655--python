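"""CATaDa chromatin accessibility and signal-profile analytics.

Untethered Dam methylation tracks chromatin accessibility, so the
RPM-normalised Dam-only control doubles as an accessibility assay.
This module calls accessible regions from that track, builds average
signal profiles (metaprofiles) and heatmap matrices around region
centres, correlates binding with accessibility, and summarises signal
over labelled chromatin-state maps.

Profiles average log2 fragment values directly (no linearisation) and
weight fragments by their bp overlap with each bin, so the irregular
GATC grid projects consistently onto the regular profile grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Region, RegionSet
from .tracks import FragmentTrack, replicate_concordance

__all__ = [
    "MetaProfile",
    "StateEnrichment",
    "call_accessible_regions",
    "metaprofile",
    "binding_accessibility_correlation",
    "state_enrichment",
    "DEFAULT_ACCESS_QUANTILE",
    "DEFAULT_CRM_FLANK",
    "DEFAULT_OPEN_FLANK",
]

DEFAULT_ACCESS_QUANTILE = 0.95
DEFAULT_CRM_FLANK = 10_000  # bp around CRM/enhancer centres
DEFAULT_OPEN_FLANK = 2_000  # bp around open-chromatin centres


@dataclass
class MetaProfile:
    """Per-region signal matrix on a regular grid around region centres.

    ``matrix`` is regions x bins (NaN = missing bin); ``weights`` holds
    the covered non-missing bp behind each entry.  ``mean_profile`` is
    the column-wise mean ignoring missing entries.
    """

    bin_centers: np.ndarray  # bp, relative to region centre
    matrix: np.ndarray
    weights: np.ndarray
    mean_profile: np.ndarray
    bin_width: int
    flank: int

    def heatmap_order(self) -> np.ndarray:
        """Row indices by descending mean row signal (NaN rows last)."""
        row_means = np.nanmean(np.where(np.isnan(self.matrix), np.nan, self.matrix), axis=1)
        key = np.where(np.isnan(row_means), -np.inf, row_means)
        return np.argsort(-key, kind="stable")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin_{int(c)}" for c in self.bin_centers]
        return pd.DataFrame(self.matrix, columns=cols)

    def mean_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.bin_centers.astype(int), "mean": self.mean_profile})


@dataclass
class StateEnrichment:
    """Length-weighted mean signal per chromatin state.

    ``enrichment`` = state mean - genome-wide (length-weighted) mean;
    states with no covered, non-missing fragment are reported missing
    (absent from both dicts, listed in ``missing_states``).
    """

    state_means: dict[str, float]
    enrichment: dict[str, float]
    genome_mean: float
    missing_states: list[str]

    def to_frame(self) -> pd.DataFrame:
        states = sorted(self.state_means)
        return pd.DataFrame(
            {
                "state": states,
                "mean_signal": [self.state_means[s] for s in states],
                "enrichment": [self.enrichment[s] for s in states],
            }
        )


# ---------------------------------------------------------------------------
# accessible-region calling
# ---------------------------------------------------------------------------

def call_accessible_regions(
    dam_only_rpm: FragmentTrack,
    threshold_quantile: float = DEFAULT_ACCESS_QUANTILE,
    min_fragments: int = 2,
) -> RegionSet:
    """Runs of >= min_fragments fragments at or above a genome-wide RPM quantile.

    Inclusion is >= the quantile value, so fragments tied with the
    threshold (which happens when the top of the distribution is flat)
    still form regions; as a guard for mostly-flat tracks, a fragment
    must also strictly exceed the genome-wide median.  For continuous
    RPM data both refinements coincide with a plain strict cut.
    """
    from .peaks import _runs  # run machinery shared with the peak caller

    if not 0.0 < threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must be in (0, 1)")
    usable = dam_only_rpm.values[~dam_only_rpm.missing]
    if usable.size == 0:
        raise ValueError("track has no usable fragments")
    if np.all(usable == usable[0]):
        raise ValueError(
            "all fragment values are equal: the quantile threshold is undefined "
            "for run detection on a degenerate track"
        )
    threshold = float(np.quantile(usable, threshold_quantile))
    median = float(np.median(usable))
    above = (
        (~dam_only_rpm.missing)
        & (dam_only_rpm.values >= threshold)
        & (dam_only_rpm.values > median)
    )
    regions = []
    fmap = dam_only_rpm.fmap
    for chrom, sl in fmap.chrom_slices():
        b = fmap.boundaries(chrom)
        starts, stops = _runs(above[sl], min_fragments)
        for s, e in zip(starts, stops):
            regions.append(Region(chrom, int(b[s]), int(b[e])))
    return RegionSet("accessible", regions, fmap.genome())


# ---------------------------------------------------------------------------
# metaprofiles
# ---------------------------------------------------------------------------

def metaprofile(
    track: FragmentTrack, regions: RegionSet, flank: int, bin_width: int
) -> MetaProfile:
    """Project the track onto bins centred on each region midpoint.

    Each bin value is the length-weighted mean of overlapping
    non-missing fragment values; bins off-chromosome or fully missing
    come back NaN.  Region centre for even-length regions is
    floor((start + end) / 2).
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if bin_width <= 0 or flank <= 0:
        raise ValueError("flank and bin_width must be positive")
    if flank % bin_width != 0:
        raise ValueError(f"flank ({flank}) must be a multiple of bin_width ({bin_width})")
    n_bins = 2 * flank // bin_width
    rel_edges = np.arange(-flank, flank + bin_width, bin_width)
    bin_centers = (rel_edges[:-1] + rel_edges[1:]) / 2.0

    fmap = track.fmap
    matrix = np.full((len(regions), n_bins), np.nan)
    weights = np.zeros((len(regions), n_bins))
    safe = np.where(track.missing, 0.0, track.values)
    for ri, region in enumerate(regions):
        if region.chrom not in fmap.chroms:
            continue
        b = fmap.boundaries(region.chrom)
        off = fmap.offset(region.chrom)
        centre = (region.start + region.end) // 2
        for bi in range(n_bins):
            lo = centre + int(rel_edges[bi])
            hi = centre + int(rel_edges[bi + 1])
            lo_c, hi_c = max(lo, 0), min(hi, int(b[-1]))
            if lo_c >= hi_c:
                continue
            i0 = int(np.searchsorted(b, lo_c, side="right") - 1)
            i1 = int(np.searchsorted(b, hi_c, side="left"))
            wsum = w = 0.0
            for i in range(i0, i1):
                if track.missing[off + i]:
                    continue
                ov = min(hi_c, int(b[i + 1])) - max(lo_c, int(b[i]))
                if ov > 0:
                    wsum += safe[off + i] * ov
                    w += ov
            if w > 0:
                matrix[ri, bi] = wsum / w
                weights[ri, bi] = w
    with np.errstate(invalid="ignore"):
        mean_profile = np.nanmean(matrix, axis=0)
    return MetaProfile(bin_centers, matrix, weights, mean_profile, bin_width, flank)


def binding_accessibility_correlation(
    binding: FragmentTrack, accessibility: FragmentTrack
) -> float:
    """Spearman correlation of binding vs accessibility per GATC fragment."""
    return replicate_concordance(binding, accessibility)


# ---------------------------------------------------------------------------
# chromatin-state enrichment
# ---------------------------------------------------------------------------

def state_enrichment(track: FragmentTrack, states: RegionSet) -> StateEnrichment:
    """Length-weighted mean signal per labelled state vs the genome mean.

    State intervals may abut but not overlap; every labelled interval
    contributes to exactly one state.
    """
    by_chrom = states.by_chrom()
    for chrom, regs in by_chrom.items():
        for a, b in zip(regs, regs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping state intervals on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
    labels = {r.name for r in states}
    if None in labels or not labels:
        raise ValueError("every state interval needs a non-empty label")

    fmap = track.fmap
    frag_len = fmap.lengths.astype(float)
    nonmiss = ~track.missing
    genome_w = float(frag_len[nonmiss].sum())
    if genome_w == 0:
        raise ValueError("track has no usable fragments")
    genome_mean = float((track.values[nonmiss] * frag_len[nonmiss]).sum() / genome_w)

    sums: dict[str, float] = {s: 0.0 for s in labels}
    wts: dict[str, float] = {s: 0.0 for s in labels}
    for chrom, regs in by_chrom.items():
        if chrom not in fmap.chroms:
            continue
        b = fmap.boundaries(chrom)
        off = fmap.offset(chrom)
        for r in regs:
            lo, hi = max(r.start, 0), min(r.end, int(b[-1]))
            if lo >= hi:
                continue
            i0 = int(np.searchsorted(b, lo, side="right") - 1)
            i1 = int(np.searchsorted(b, hi, side="left"))
            for i in range(i0, i1):
                if track.missing[off + i]:
                    continue
                ov = min(hi, int(b[i + 1])) - max(lo, int(b[i]))
                if ov > 0:
                    sums[r.name] += track.values[off + i] * ov
                    wts[r.name] += ov
    state_means, enrich, missing = {}, {}, []
    for s in sorted(labels):
        if wts[s] > 0:
            state_means[s] = sums[s] / wts[s]
            enrich[s] = state_means[s] - genome_mean
        else:
            missing.append(s)
    return StateEnrichment(state_means, enrich, genome_mean, missing)
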