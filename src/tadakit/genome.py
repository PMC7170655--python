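"""Genome coordinate model for DamID analysis.

GATC fragment maps, gene annotations and region sets, plus readers and
writers for the plain-text genomics formats the pipeline exchanges
(FASTA, BED, bedGraph, GFF3).

All *internal* coordinates are 0-based half-open.  GFF3 is 1-based
closed on disk; the conversion happens here, at the file boundary, and
nowhere else.  BED and bedGraph are already 0-based half-open.

The :class:`FragmentMap` is the coordinate system of every downstream
signal: DamID methylation can only be read out between GATC motifs, so
the genomic interval between consecutive motifs ("GATC fragment") is
the native resolution unit of the assay.  The boundary convention is
fixed here once: a fragment boundary sits at the *first* base of each
GATC occurrence, so the 4 bp of the motif belong to the downstream
fragment.  Any consistent convention preserves downstream statistics;
one is chosen for reproducibility.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeIndex",
    "FragmentMap",
    "GeneModel",
    "Region",
    "RegionSet",
    "build_fragment_map",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_gff3",
    "read_region_bed",
    "write_bed",
    "fragment_map_from_bed",
]

# IUPAC nucleotide one-letter codes (plus U); ambiguity codes never match GATC.
_IUPAC = frozenset("ACGTURYSWKMBDHVN")
_GATC = re.compile("GATC")


class GenomeIndex:
    """Ordered chromosome name -> length table."""

    def __init__(self, lengths: Mapping[str, int]):
        if not lengths:
            raise ValueError("GenomeIndex requires at least one chromosome")
        for name, ln in lengths.items():
            if int(ln) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {ln}")
        self._lengths = {str(k): int(v) for k, v in lengths.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and self._lengths == other._lengths

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenomeIndex({self._lengths!r})"


class FragmentMap:
    """Ordered GATC fragments tiling each chromosome.

    Stored as one boundary array per chromosome (first element 0, last
    element the chromosome length); fragment *i* of a chromosome is
    ``[boundaries[i], boundaries[i+1])``.  Fragments of all chromosomes
    are additionally exposed as flat, concatenated arrays so that
    signal tracks can be plain 1-D vectors.
    """

    def __init__(self, boundaries: Mapping[str, Sequence[int]]):
        if not boundaries:
            raise ValueError("FragmentMap requires at least one chromosome")
        self._boundaries: dict[str, np.ndarray] = {}
        for chrom, b in boundaries.items():
            arr = np.asarray(b, dtype=np.int64)
            if arr.ndim != 1 or arr.size < 2:
                raise ValueError(f"{chrom}: need at least one fragment")
            if arr[0] != 0:
                raise ValueError(f"{chrom}: first boundary must be 0, got {arr[0]}")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{chrom}: boundaries must be strictly increasing")
            self._boundaries[str(chrom)] = arr
        # flat views
        self._offsets: dict[str, int] = {}
        starts, ends = [], []
        off = 0
        for chrom, b in self._boundaries.items():
            self._offsets[chrom] = off
            starts.append(b[:-1])
            ends.append(b[1:])
            off += b.size - 1
        self.starts = np.concatenate(starts)
        self.ends = np.concatenate(ends)

    # -- basic queries -------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return list(self._boundaries)

    @property
    def n_fragments(self) -> int:
        return int(self.starts.size)

    @property
    def lengths(self) -> np.ndarray:
        """Per-fragment lengths in bp (flat order)."""
        return self.ends - self.starts

    def boundaries(self, chrom: str) -> np.ndarray:
        return self._boundaries[chrom]

    def n_fragments_of(self, chrom: str) -> int:
        return self._boundaries[chrom].size - 1

    def offset(self, chrom: str) -> int:
        """Flat index of the first fragment of *chrom*."""
        return self._offsets[chrom]

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """(chrom, flat-index slice) pairs in chromosome order."""
        out = []
        for chrom in self._boundaries:
            o = self._offsets[chrom]
            out.append((chrom, slice(o, o + self.n_fragments_of(chrom))))
        return out

    def genome(self) -> GenomeIndex:
        return GenomeIndex({c: int(b[-1]) for c, b in self._boundaries.items()})

    def locate(self, chrom: str, pos: int) -> int:
        """Flat index of the fragment containing base *pos*."""
        b = self._boundaries[chrom]
        if not 0 <= pos < b[-1]:
            raise ValueError(f"position {pos} outside {chrom} [0,{b[-1]})")
        return self._offsets[chrom] + int(np.searchsorted(b, pos, side="right") - 1)

    def fragments(self) -> Iterator[tuple[str, int, int]]:
        for chrom, b in self._boundaries.items():
            for s, e in zip(b[:-1], b[1:]):
                yield chrom, int(s), int(e)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FragmentMap)
            and self.chroms == other.chroms
            and all(np.array_equal(self._boundaries[c], other._boundaries[c]) for c in self.chroms)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<FragmentMap {len(self.chroms)} chromosomes, {self.n_fragments} fragments>"

    # -- serialisation -------------------------------------------------
    def to_bed(self) -> str:
        lines = [f"{c}\t{s}\t{e}" for c, s, e in self.fragments()]
        return "\n".join(lines) + "\n"


def build_fragment_map(sequences: Mapping[str, str]) -> FragmentMap:
    """Cut each chromosome at every literal GATC motif.

    Boundaries are placed at the first base of each (case-insensitive)
    GATC occurrence; chromosome ends close the terminal fragments.  A
    chromosome without any motif yields a single fragment spanning it.
    Ambiguity codes (N etc.) never match.
    """
    boundaries: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        if len(seq) == 0:
            raise ValueError(f"chromosome {chrom!r}: empty sequence")
        up = str(seq).upper()
        bad = set(up) - _IUPAC
        if bad:
            ch = sorted(bad)[0]
            raise ValueError(f"chromosome {chrom!r}: non-nucleotide character {ch!r}")
        cuts = [m.start() for m in _GATC.finditer(up)]
        b = [0] + [c for c in cuts if c != 0] + [len(up)]
        boundaries[chrom] = np.asarray(b, dtype=np.int64)
    return FragmentMap(boundaries)


def fragment_map_from_bed(source) -> FragmentMap:
    """Rebuild a FragmentMap from a fragment BED (as written by to_bed)."""
    boundaries: dict[str, list[int]] = {}
    for lineno, fields in _bed_rows(source):
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        b = boundaries.setdefault(chrom, [])
        if not b:
            if start != 0:
                raise ValueError(f"line {lineno}: first fragment of {chrom} must start at 0")
            b.append(start)
        elif start != b[-1]:
            raise ValueError(f"line {lineno}: fragments of {chrom} do not tile (gap at {start})")
        b.append(end)
    if not boundaries:
        raise ValueError("empty fragment BED")
    return FragmentMap(boundaries)


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene: span, strand, and exon structure.

    TSS is the strand-aware 5' end (``start`` on +, ``end - 1`` on -);
    TTS is the 3' end.  Coordinates 0-based half-open.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end ({self.end}) <= start ({self.start})")
        for (s, e) in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class Region:
    """A genomic interval with optional BED columns 4-6."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"region {self.chrom}:{self.start}-{self.end}: start >= end")


class RegionSet:
    """A named collection of intervals (CRMs, chromatin states, peaks...)."""

    def __init__(self, name: str, regions: Iterable[Region], genome: GenomeIndex | None = None):
        self.name = name
        self.regions = list(regions)
        self.genome = genome
        if genome is not None:
            for r in self.regions:
                if r.chrom not in genome:
                    raise ValueError(f"region on unknown chromosome {r.chrom!r}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def sorted(self) -> "RegionSet":
        return RegionSet(self.name, sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end)), self.genome)

    def by_chrom(self) -> dict[str, list[Region]]:
        out: dict[str, list[Region]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        for v in out.values():
            v.sort(key=lambda r: (r.start, r.end))
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered {name: sequence} dict."""
    handle = _as_handle(source)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
    if not seqs:
        raise ValueError("no FASTA records found")
    return seqs


def write_fasta(sequences: Mapping[str, str], dest=None, width: int = 70) -> str:
    lines = []
    for name, seq in sequences.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    text = "\n".join(lines) + "\n"
    return _write_text(text, dest)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_annotation(source) -> list[GeneModel]:
    """Parse gene (and exon) features from GFF3 into GeneModel records.

    GFF3 is 1-based closed; spans come back 0-based half-open.  Genes
    are sorted by (chrom, start); duplicate gene ids are rejected.
    Exon features are attached to their gene via the Parent attribute.
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order = 0
    for lineno, line in _text_lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 9:
            raise ValueError(f"GFF3 line {lineno}: expected 9 tab-separated columns, got {len(cols)}")
        chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cols
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"GFF3 line {lineno}: non-integer coordinate") from exc
        if end1 < start1:
            raise ValueError(f"GFF3 line {lineno}: end ({end1}) < start ({start1})")
        attrs = _parse_gff_attrs(attrs_s)
        if ftype == "gene":
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"GFF3 line {lineno}: gene without ID or gene_id attribute")
            if gid in genes:
                raise ValueError(f"GFF3 line {lineno}: duplicate gene_id {gid!r}")
            genes[gid] = dict(chrom=chrom, strand=strand, start=start1 - 1, end=end1, order=order)
            order += 1
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent is not None:
                exons.setdefault(parent, []).append((start1 - 1, end1))
    models = [
        GeneModel(
            gene_id=gid,
            chrom=g["chrom"],
            strand=g["strand"],
            start=g["start"],
            end=g["end"],
            exons=tuple(sorted(exons.get(gid, []))),
        )
        for gid, g in genes.items()
    ]
    models.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return models


def write_gff3(genes: Sequence[GeneModel], dest=None) -> str:
    """Write GeneModels as GFF3 gene + exon features (sorted)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)):
        lines.append(
            f"{g.chrom}\ttadakit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                f"{g.chrom}\ttadakit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.e{i};Parent={g.gene_id}"
            )
    text = "\n".join(lines) + "\n"
    return _write_text(text, dest)


def _parse_gff_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_region_bed(source, name: str = "regions", genome: GenomeIndex | None = None) -> RegionSet:
    """Read BED3-BED6 into a RegionSet; columns 4-6 preserved when present."""
    regions = []
    for lineno, fields in _bed_rows(source):
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"BED line {lineno}: non-integer coordinate") from exc
        if start >= end:
            raise ValueError(f"BED line {lineno}: start ({start}) >= end ({end})")
        label = fields[3] if len(fields) > 3 else None
        score = float(fields[4]) if len(fields) > 4 else None
        strand = fields[5] if len(fields) > 5 else None
        regions.append(Region(chrom, start, end, label, score, strand))
    return RegionSet(name, regions, genome)


def write_bed(regions: RegionSet, dest=None) -> str:
    """Write a RegionSet as sorted BED; optional columns padded with '.'."""
    lines = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        fields = [r.chrom, str(r.start), str(r.end)]
        ncols = 3
        if r.strand is not None:
            ncols = 6
        elif r.score is not None:
            ncols = 5
        elif r.name is not None:
            ncols = 4
        if ncols >= 4:
            fields.append(r.name if r.name is not None else ".")
        if ncols >= 5:
            fields.append(_fmt_score(r.score) if r.score is not None else ".")
        if ncols >= 6:
            fields.append(r.strand)
        lines.append("\t".join(fields))
    text = ("\n".join(lines) + "\n") if lines else ""
    return _write_text(text, dest)


def _fmt_score(x: float) -> str:
    return format(x, "g")


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _as_handle(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    text = Path(source).read_text()
    return io.StringIO(text)


def _text_lines(source) -> Iterator[tuple[int, str]]:
    handle = _as_handle(source)
    for lineno, line in enumerate(handle, 1):
        yield lineno, line


def _bed_rows(source) -> Iterator[tuple[int, list[str]]]:
    for lineno, line in _text_lines(source):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        yield lineno, fields


def _write_text(text: str, dest) -> str:
    if dest is None:
        return text
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
    return text
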