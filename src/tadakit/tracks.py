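"""Per-GATC-fragment signal tracks.

A DamID experiment yields read counts per GATC fragment for a
Dam-fusion sample and an untethered Dam-only control.  The control
serves two purposes: it normalises the fusion signal into a log2
occupancy ratio (binding), and — because free Dam preferentially
methylates open chromatin — it doubles as a chromatin-accessibility
readout (CATaDa) after reads-per-million scaling.

Note that because the fusion track is normalised against the Dam-only
control, "negative peaks" (log2 ratio < 0) are expected wherever
control methylation exceeds the fusion signal; they indicate depleted
binding at accessible sites, not an artefact.

Fragments with zero reads in *both* samples carry no information and
are flagged missing; missing fragments are excluded from peak calling,
correlations and profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FragmentMap, _as_handle, _write_text

__all__ = [
    "CountTrack",
    "FragmentTrack",
    "rpm_normalize",
    "occupancy_ratio",
    "replicate_concordance",
    "read_bedgraph",
    "write_bedgraph",
    "track_to_frame",
]

DEFAULT_PSEUDOCOUNT = 0.5  # RPM units; recorded in output headers


@dataclass
class CountTrack:
    """Non-negative integer read counts aligned to a FragmentMap."""

    fmap: FragmentMap
    counts: np.ndarray
    total_reads: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size != self.fmap.n_fragments:
            raise ValueError(
                f"count vector length {self.counts.size} != fragment count {self.fmap.n_fragments}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")


@dataclass
class FragmentTrack:
    """Real-valued per-fragment signal with a missing-data mask.

    ``units`` documents the scale: "log2" for occupancy ratios, "RPM"
    for accessibility.  ``missing`` is True where the fragment carries
    no information.
    """

    fmap: FragmentMap
    values: np.ndarray
    missing: np.ndarray
    units: str = "log2"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.size != self.fmap.n_fragments:
            raise ValueError(
                f"value vector length {self.values.size} != fragment count {self.fmap.n_fragments}"
            )
        if self.missing.size != self.values.size:
            raise ValueError("missing mask and values must have the same length")
        if not np.all(np.isfinite(self.values[~self.missing])):
            raise ValueError("non-missing values must be finite")

    @property
    def n_usable(self) -> int:
        return int((~self.missing).sum())


def rpm_normalize(counts: CountTrack) -> FragmentTrack:
    """Scale counts to reads per million: ``count * 1e6 / total_reads``."""
    values = counts.counts * (1e6 / counts.total_reads)
    return FragmentTrack(counts.fmap, values, np.zeros(values.size, dtype=bool), units="RPM")


def occupancy_ratio(
    fusion: CountTrack, control: CountTrack, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> FragmentTrack:
    """log2 (fusion RPM + pc) / (control RPM + pc) per fragment.

    Fragments with zero reads in both samples are flagged missing.
    """
    if fusion.fmap is not control.fmap and fusion.fmap != control.fmap:
        raise ValueError("fusion and control tracks are on different fragment maps")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    rf = rpm_normalize(fusion).values
    rc = rpm_normalize(control).values
    values = np.log2((rf + pseudocount) / (rc + pseudocount))
    missing = (fusion.counts == 0) & (control.counts == 0)
    values = np.where(missing, 0.0, values)
    return FragmentTrack(fusion.fmap, values, missing, units="log2")


def replicate_concordance(track_a: FragmentTrack, track_b: FragmentTrack) -> float:
    """Spearman rank correlation over jointly non-missing fragments."""
    if track_a.fmap is not track_b.fmap and track_a.fmap != track_b.fmap:
        raise ValueError("tracks are on different fragment maps")
    usable = ~track_a.missing & ~track_b.missing
    if usable.sum() < 3:
        raise ValueError(f"need >= 3 jointly non-missing fragments, got {int(usable.sum())}")
    rho = stats.spearmanr(track_a.values[usable], track_b.values[usable]).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_bedgraph(track: FragmentTrack, dest=None, header: str | None = None) -> str:
    """One bedGraph record per non-missing fragment (missing = no coverage)."""
    lines = [] if header is None else [f"# {header}"]
    starts, ends = track.fmap.starts, track.fmap.ends
    for chrom, sl in track.fmap.chrom_slices():
        for i in range(sl.start, sl.stop):
            if track.missing[i]:
                continue
            lines.append(f"{chrom}\t{starts[i]}\t{ends[i]}\t{format(track.values[i], 'g')}")
    text = ("\n".join(lines) + "\n") if lines else ""
    return _write_text(text, dest)


def read_bedgraph(source, fmap: FragmentMap, units: str = "log2") -> FragmentTrack:
    """Project bedGraph values onto a FragmentMap.

    Records exactly matching fragment boundaries attach directly;
    otherwise values are length-weighted onto overlapping fragments.
    Fragments with no covering record come back missing.
    """
    wsum = np.zeros(fmap.n_fragments)
    wlen = np.zeros(fmap.n_fragments)
    chroms = set(fmap.chroms)
    handle = _as_handle(source)
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"bedGraph line {lineno}: fewer than 4 columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if start >= end:
            raise ValueError(f"bedGraph line {lineno}: start >= end")
        if chrom not in chroms:
            raise ValueError(f"bedGraph line {lineno}: unknown chromosome {chrom!r}")
        b = fmap.boundaries(chrom)
        off = fmap.offset(chrom)
        start = max(start, 0)
        end = min(end, int(b[-1]))
        if start >= end:
            continue
        i0 = int(np.searchsorted(b, start, side="right") - 1)
        i1 = int(np.searchsorted(b, end, side="left"))
        for i in range(i0, i1):
            ov = min(end, int(b[i + 1])) - max(start, int(b[i]))
            if ov > 0:
                wsum[off + i] += value * ov
                wlen[off + i] += ov
    missing = wlen == 0
    values = np.where(missing, 0.0, wsum / np.where(missing, 1.0, wlen))
    return FragmentTrack(fmap, values, missing, units=units)


def track_to_frame(track: FragmentTrack) -> pd.DataFrame:
    """Tab-table form: chrom, start, end, value, missing_flag."""
    chrom_col = np.empty(track.fmap.n_fragments, dtype=object)
    for chrom, sl in track.fmap.chrom_slices():
        chrom_col[sl] = chrom
    return pd.DataFrame(
        {
            "chrom": chrom_col,
            "start": track.fmap.starts,
            "end": track.fmap.ends,
            "value": track.values,
            "missing_flag": track.missing.astype(int),
        }
    )
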