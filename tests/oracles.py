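"""Independent brute-force reference implementations.

Deliberately simple and slow: explicit loops, exhaustive enumeration,
no shared code with the package internals.  These pin down the
semantics of every core operation on small instances.
"""

from __future__ import annotations

import math
import re

import numpy as np


def motif_positions(seq: str, motif: str = "GATC") -> list[int]:
    """Every occurrence start, by exhaustive windowed comparison."""
    s = seq.upper()
    return [i for i in range(len(s) - len(motif) + 1) if s[i : i + len(motif)] == motif]


def naive_runs(values, missing, threshold, min_fragments):
    """All maximal above-threshold runs as (start_idx, stop_idx, n, mean)."""
    out = []
    i = 0
    n = len(values)
    while i < n:
        if not missing[i] and values[i] > threshold:
            j = i
            while j < n and not missing[j] and values[j] > threshold:
                j += 1
            if j - i >= min_fragments:
                seg = [values[k] for k in range(i, j)]
                out.append((i, j, j - i, sum(seg) / len(seg)))
            i = j
        else:
            i += 1
    return out


def naive_fdr(values, missing, candidates, n_shuffles, seed, threshold=0.0, min_fragments=2):
    """Shuffle-null FDRs, replaying the production permutation stream."""
    values = np.asarray(values, dtype=float)
    missing = np.asarray(missing, dtype=bool)
    rng = np.random.default_rng(seed)
    base = values[~missing]
    positions = [i for i in range(len(values)) if not missing[i]]
    null = []
    for _ in range(n_shuffles):
        perm = rng.permutation(base)
        pv = values.copy()
        for pos, v in zip(positions, perm):
            pv[pos] = v
        null.extend((n, m) for (_s, _e, n, m) in naive_runs(pv, missing, threshold, min_fragments))
    obs = [(p.n_fragments, p.mean_occupancy) for p in candidates]
    raw = []
    for n0, m0 in obs:
        null_tail = sum(1 for (n, m) in null if n >= n0 and m >= m0) / n_shuffles
        obs_tail = sum(1 for (n, m) in obs if n >= n0 and m >= m0)
        raw.append(min(max(null_tail / obs_tail, 0.0), 1.0))
    # q-value monotonisation: best estimate among dominated thresholds
    fdrs = []
    for n0, m0 in obs:
        fdrs.append(min(r for (n, m), r in zip(obs, raw) if n <= n0 and m <= m0))
    return fdrs


def naive_intersect(rep1, rep2):
    """Union spans of overlap-graph components containing both replicates.

    Connected components via networkx on the all-pairs overlap graph.
    """
    import networkx as nx

    peaks = [(p, 0) for p in rep1] + [(p, 1) for p in rep2]
    g = nx.Graph()
    g.add_nodes_from(range(len(peaks)))
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            a, b = peaks[i][0], peaks[j][0]
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                g.add_edge(i, j)
    out = []
    for comp in nx.connected_components(g):
        tags = {peaks[i][1] for i in comp}
        if tags != {0, 1}:
            continue
        members = [peaks[i][0] for i in comp]
        out.append(
            (members[0].chrom, min(p.start for p in members), max(p.end for p in members))
        )
    return sorted(out)


def naive_assign(peaks, genes, max_distance):
    """(peak_index, gene_id, distance) by exhaustive triple loop."""
    out = []
    for pi, p in enumerate(peaks):
        for g in genes:
            if g.chrom != p.chrom:
                continue
            if g.start < p.end and p.start < g.end:
                out.append((pi, g.gene_id, 0))
                continue
            if g.start >= p.end:
                gap = g.start - p.end
                lo, hi = p.end, g.start
            else:
                gap = p.start - g.end
                lo, hi = g.end, p.start
            if gap > max_distance:
                continue
            blocked = False
            for other in genes:
                if other.gene_id == g.gene_id or other.chrom != p.chrom:
                    continue
                if other.start >= lo and other.end <= hi:
                    blocked = True
                    break
            if not blocked:
                out.append((pi, g.gene_id, gap))
    return sorted(set(out))


def naive_classify(peaks, genes, promoter_window=(1000, 100), tts_window=100):
    """Per-peak feature category by explicit per-gene checks."""
    cats = []
    up, down = promoter_window
    for p in peaks:
        mid = (p.start + p.end) // 2
        promoter = tts = exon = gene_body = False
        for g in genes:
            if g.chrom != p.chrom:
                continue
            rel = (mid - g.tss) if g.strand == "+" else (g.tss - mid)
            if -up <= rel <= down:
                promoter = True
            if abs(mid - g.tts) <= tts_window:
                tts = True
            if g.start <= mid < g.end:
                gene_body = True
                exon_list = g.exons if g.exons else ((g.start, g.end),)
                for (s, e) in exon_list:
                    if s <= mid < e:
                        exon = True
        if promoter:
            cats.append("promoter-TSS")
        elif tts:
            cats.append("TTS")
        elif exon:
            cats.append("exon")
        elif gene_body:
            cats.append("intron")
        else:
            cats.append("intergenic")
    return cats


def hypergeom_upper_tail(k, size_a, size_b, size_u):
    """P(X >= k) for X ~ Hypergeom by direct pmf summation (math.comb)."""
    total = 0
    denom = math.comb(size_u, size_b)
    for x in range(k, min(size_a, size_b) + 1):
        total += math.comb(size_a, x) * math.comb(size_u - size_a, size_b - x)
    return total / denom


def naive_spearman(xs, ys):
    """Spearman rho via explicit average ranks and the Pearson formula."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(xs)), ranks(list(ys))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def naive_state_means(track_values, track_missing, boundaries, regions):
    """Length-weighted per-label means on a single chromosome."""
    sums: dict[str, float] = {}
    wts: dict[str, float] = {}
    n = len(boundaries) - 1
    for (start, end, label) in regions:
        for i in range(n):
            fs, fe = boundaries[i], boundaries[i + 1]
            ov = min(end, fe) - max(start, fs)
            if ov > 0 and not track_missing[i]:
                sums[label] = sums.get(label, 0.0) + track_values[i] * ov
                wts[label] = wts.get(label, 0.0) + ov
    return {lab: sums[lab] / wts[lab] for lab in sums if wts[lab] > 0}


def naive_bin_value(track_values, track_missing, boundaries, lo, hi):
    """Length-weighted mean of fragment values over [lo, hi); None if empty."""
    n = len(boundaries) - 1
    wsum = w = 0.0
    for i in range(n):
        fs, fe = boundaries[i], boundaries[i + 1]
        ov = min(hi, fe) - max(lo, fs)
        if ov > 0 and not track_missing[i]:
            wsum += track_values[i] * ov
            w += ov
    return (wsum / w) if w > 0 else None
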