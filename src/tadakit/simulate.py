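"""Synthetic DamID study generator with known ground truth.

Every input the pipeline consumes can be generated here: chromosomes
with a controlled GATC grid, gene annotations, replicate fusion /
Dam-only fragment counts with planted bound regions of known log2
effect, chromatin-accessibility structure, chromatin-state maps, DE
tables with a controlled bound-gene overlap, and FPKM tissue matrices.

The count model is deliberately minimal but captures the two features
that matter for the statistics downstream: overdispersion (negative
binomial with dispersion alpha, var = mu + alpha * mu^2) and the
accessibility confound (untethered Dam methylates open chromatin more,
so Dam-only counts track a per-fragment accessibility multiplier that
the fusion sample shares).  Planted bound regions multiply the fusion
mean by 2^effect over whole runs of consecutive fragments, emulating
the broad binding the assay detects.

Determinism: every generator is a pure function of (config, seed).
Sub-streams are derived by stable labelled splitting (CRC32 of the
label as a SeedSequence spawn key), so adding a generator never
perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import FragmentMap, GeneModel, Region, RegionSet, build_fragment_map
from .tracks import CountTrack

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_genome",
    "simulate_annotation",
    "simulate_truth",
    "simulate_damid",
    "simulate_de_table",
    "simulate_fpkm_matrix",
    "simulate_states",
    "simulate_dataset",
]

_MOTIF = "GATC"

STATE_PALETTE = (
    "black",
    "HP1",
    "PcG-repressive",
    "TrxG-repressive",
    "TrxG",
    "non-TrxG",
    "PcG",
)

TISSUES = ("CNS", "Fatbody", "Hindgut", "Midgut", "SalivaryGland", "Tubules")


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults for a desk-size simulated TaDa experiment."""

    n_chromosomes: int = 1
    chrom_length: int = 3_000_000
    mean_gatc_spacing: int = 200  # bp between motif starts (4-cutter-like density)
    n_genes: int = 300  # ~1 gene / 10 kb
    coverage: float = 50.0  # mean reads per average-length fragment (control)
    dispersion: float = 0.005  # NB alpha; 0 = Poisson
    n_bound_regions: int = 8
    effect_log2: float = 2.0
    min_region_fragments: int = 3
    max_region_fragments: int = 8
    n_replicates: int = 2
    accessibility_sigma: float = 1.0  # lognormal sd of the open-chromatin component
    accessibility_floor: float = 0.6  # basal methylation of closed chromatin
    low_accessibility_fraction: float = 0.8  # bound regions targeted to closed chromatin

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.mean_gatc_spacing < len(_MOTIF):
            raise ValueError("mean GATC spacing must be at least the motif length (4 bp)")
        if self.mean_gatc_spacing < 50:
            raise ValueError("mean GATC spacing below 50 bp is unrealistically dense")
        if self.coverage < 0 or self.dispersion < 0:
            raise ValueError("coverage and dispersion must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not 0.0 <= self.low_accessibility_fraction <= 1.0:
            raise ValueError("low_accessibility_fraction must be in [0, 1]")
        if not 1 <= self.min_region_fragments <= self.max_region_fragments:
            raise ValueError("invalid bound-region fragment range")


@dataclass
class SimTruth:
    """Planted ground truth: bound regions, accessibility, seeds, parameters."""

    config: SimConfig
    seed: int
    regions: list[Region]  # name carries the planted log2 effect
    effects: np.ndarray  # per-fragment planted log2 effect (0 outside regions)
    accessibility: np.ndarray  # per-fragment multiplier, mean 1

    def region_effects(self) -> list[tuple[Region, float]]:
        return [(r, float(r.score)) for r in self.regions]

    def to_bed(self) -> str:
        lines = [
            f"{r.chrom}\t{r.start}\t{r.end}\tbound_{i}\t{format(r.score, 'g')}\t."
            for i, r in enumerate(self.regions, 1)
        ]
        return ("\n".join(lines) + "\n") if lines else ""


def _child_rng(seed: int, label: str) -> np.random.Generator:
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _random_background(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_genome(config: SimConfig, seed: int) -> tuple[dict[str, str], FragmentMap]:
    """Random chromosomes with GATC motifs placed as a renewal process.

    Gaps between motif starts are 4 bp (the motif) plus an exponential
    draw with mean ``mean_gatc_spacing - 4``.  Accidental motifs in the
    random background are disrupted (final C -> T, which provably
    cannot create a new occurrence), so the planted positions are
    exactly the fragment boundaries.
    """
    rng = _child_rng(seed, "genome")
    seqs: dict[str, str] = {}
    for ci in range(config.n_chromosomes):
        length = config.chrom_length
        codes = _random_background(rng, length)
        seq = bytearray(_BASES[codes].tobytes())
        # plant motif starts
        positions = []
        pos = float(rng.exponential(config.mean_gatc_spacing))
        while pos + 4 <= length:
            positions.append(int(pos))
            pos += 4 + float(rng.exponential(config.mean_gatc_spacing - 4))
        for p in positions:
            seq[p : p + 4] = b"GATC"
        # disrupt accidental motifs outside the planted set; a single pass
        # suffices because GATC cannot overlap itself and C->T at the motif
        # end cannot create a new occurrence
        import re as _re

        planted = set(positions)
        for m in _re.finditer(b"GATC", bytes(seq)):
            if m.start() not in planted:
                seq[m.start() + 3] = ord("T")
        seqs[f"chr{ci + 1}"] = bytes(seq).decode("ascii")
    return seqs, build_fragment_map(seqs)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig, fmap: FragmentMap, seed: int) -> list[GeneModel]:
    """Non-overlapping genes with log-normal lengths and 1-5 exons each."""
    rng = _child_rng(seed, "annotation")
    if config.n_genes == 0:
        return []
    genome = fmap.genome()
    chroms = genome.chroms
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    attempts = 0
    max_attempts = 200 * config.n_genes
    while len(genes) < config.n_genes:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {config.n_genes} non-overlapping genes "
                f"after {max_attempts} attempts: gene density infeasible"
            )
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = genome[chrom]
        glen = int(np.clip(rng.lognormal(np.log(1500), 0.6), 200, clen))
        start = int(rng.integers(0, max(1, clen - glen)))
        end = start + glen
        if any(s < end and start < e for s, e in placed[chrom]):
            continue
        n_exons = int(rng.integers(1, 6))
        cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * n_exons - 2, replace=False)) if glen > 4 * n_exons else None
        if n_exons == 1 or cuts is None:
            exons = ((start, end),)
        else:
            edges = [start, *cuts.tolist(), end]
            exons = tuple((edges[2 * i], edges[2 * i + 1]) for i in range(n_exons))
        strand = "+" if rng.random() < 0.5 else "-"
        placed[chrom].append((start, end))
        genes.append(
            GeneModel(f"gene{len(genes) + 1:04d}", chrom, strand, start, end, exons)
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# ground truth and counts
# ---------------------------------------------------------------------------

def _accessibility(
    rng: np.random.Generator, n: int, sigma: float, floor: float = 0.6
) -> np.ndarray:
    """Floored, smoothed lognormal multiplier with mean 1.

    Closed chromatin keeps a basal untethered-Dam methylation rate (the
    floor); the variance sits in the open-chromatin upper tail, which
    is where CATaDa signal genuinely varies.  Smoothing makes open and
    closed domains span runs of fragments rather than single ones.
    """
    g = rng.normal(0.0, 1.0, size=n)
    w = 5
    kernel = np.ones(w) / w
    smooth = np.convolve(g, kernel, mode="same")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    open_part = np.exp(sigma * smooth) / np.exp(0.5 * sigma**2)  # mean 1
    acc = floor + (1.0 - floor) * open_part  # mean 1, minimum ~= floor
    return acc / acc.mean()


def simulate_truth(config: SimConfig, fmap: FragmentMap, seed: int) -> SimTruth:
    """Plant non-overlapping bound regions, preferentially in closed chromatin.

    A fraction ``low_accessibility_fraction`` of the regions is placed
    where the run-mean accessibility falls in the lowest tertile;
    the rest are placed uniformly.  Regions are runs of
    ``min_region_fragments``..``max_region_fragments`` consecutive GATC
    fragments at a constant planted log2 effect.
    """
    rng = _child_rng(seed, "truth")
    n = fmap.n_fragments
    acc = _accessibility(rng, n, config.accessibility_sigma, config.accessibility_floor)
    effects = np.zeros(n)
    occupied = np.zeros(n, dtype=bool)
    regions: list[Region] = []

    slices = fmap.chrom_slices()
    low_cut = np.quantile(acc, 1.0 / 3.0)
    for _ in range(config.n_bound_regions):
        L = int(rng.integers(config.min_region_fragments, config.max_region_fragments + 1))
        target_low = rng.random() < config.low_accessibility_fraction
        placedq = False
        for _try in range(200):
            chrom, sl = slices[int(rng.integers(len(slices)))]
            n_chrom = sl.stop - sl.start
            if n_chrom < L:
                continue
            s = sl.start + int(rng.integers(0, n_chrom - L + 1))
            run = slice(s, s + L)
            # one-fragment margin so neighbouring plants cannot merge
            lo = max(s - 1, 0)
            hi = min(s + L + 1, n)
            if occupied[lo:hi].any():
                continue
            if target_low and acc[run].mean() > low_cut:
                continue
            occupied[run] = True
            effects[run] = config.effect_log2
            b = fmap.boundaries(chrom)
            s_loc = s - sl.start
            regions.append(
                Region(chrom, int(b[s_loc]), int(b[s_loc + L]), None, config.effect_log2)
            )
            placedq = True
            break
        if not placedq:
            raise ValueError("could not place bound regions: genome too crowded")
    regions.sort(key=lambda r: (r.chrom, r.start))
    return SimTruth(config, seed, regions, effects, acc)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu)
    size_param = 1.0 / alpha
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def simulate_damid(truth: SimTruth, fmap: FragmentMap) -> list[tuple[CountTrack, CountTrack]]:
    """Per-replicate (fusion, control) counts from the planted truth.

    control_i ~ NB(mu = coverage * length_factor_i * accessibility_i),
    fusion_i  ~ NB(mu = control mean * 2^effect_i); replicates draw
    from independent labelled sub-streams of the master seed.
    """
    cfg = truth.config
    frag_len = fmap.lengths.astype(float)
    # methyl-PCR amplicon yield saturates: short fragments amplify nearly as
    # well as average ones and long ones do not scale linearly with length
    length_factor = np.clip(frag_len / frag_len.mean(), 0.5, 2.0)
    mu_control = cfg.coverage * length_factor * truth.accessibility
    mu_fusion = mu_control * np.power(2.0, truth.effects)
    out = []
    for r in range(cfg.n_replicates):
        rng = _child_rng(truth.seed, f"damid-rep{r + 1}")
        control = _nb_draw(rng, mu_control, cfg.dispersion)
        fusion = _nb_draw(rng, mu_fusion, cfg.dispersion)
        fus = CountTrack(fmap, fusion, max(int(fusion.sum()), 1))
        ctl = CountTrack(fmap, control, max(int(control.sum()), 1))
        out.append((fus, ctl))
    return out


# ---------------------------------------------------------------------------
# expression-side inputs
# ---------------------------------------------------------------------------

def simulate_de_table(
    bound_genes,
    universe,
    target_bound_fraction: float,
    n_up: int,
    n_down: int,
    seed: int,
) -> "pd.DataFrame":
    """DE table whose significant genes hit the bound set at a target rate.

    Each DE slot is bound with probability ``target_bound_fraction``
    (sampling without replacement within the bound / unbound pools), so
    the expected realised bound fraction equals the target.  Significant
    rows receive padj < 0.05 and |lfc| > 1; all other universe genes
    receive non-significant statistics (a small fraction get a missing
    adjusted p, as real DE output does).  Returns a DETable-compatible
    frame over the whole universe.
    """
    from .expression import DETable

    if not 0.0 <= target_bound_fraction <= 1.0:
        raise ValueError("target_bound_fraction must be in [0, 1]")
    rng = _child_rng(seed, "de")
    bound = sorted(set(bound_genes) & set(universe))
    unbound = sorted(set(universe) - set(bound))
    n_de = n_up + n_down
    n_from_bound = int(rng.binomial(n_de, target_bound_fraction))
    if n_from_bound > len(bound) or (n_de - n_from_bound) > len(unbound):
        raise ValueError(
            f"infeasible target: need {n_from_bound} bound of {len(bound)} and "
            f"{n_de - n_from_bound} unbound of {len(unbound)}"
        )
    de_genes = list(rng.choice(bound, size=n_from_bound, replace=False)) + list(
        rng.choice(unbound, size=n_de - n_from_bound, replace=False)
    )
    rng.shuffle(de_genes)
    up_set = set(de_genes[:n_up])
    down_set = set(de_genes[n_up:])

    rows = []
    for gene in sorted(set(universe)):
        if gene in up_set:
            lfc = float(rng.uniform(1.2, 4.0))
            padj = float(10 ** rng.uniform(-10, np.log10(0.049)))
        elif gene in down_set:
            lfc = float(-rng.uniform(1.2, 4.0))
            padj = float(10 ** rng.uniform(-10, np.log10(0.049)))
        else:
            lfc = float(rng.normal(0.0, 0.3))
            padj = float(rng.uniform(0.05, 1.0)) if rng.random() > 0.02 else np.nan
        rows.append((gene, lfc, padj))
    frame = pd.DataFrame(rows, columns=["gene_id", "log2_fold_change", "adjusted_p"])
    return DETable(frame)


def simulate_fpkm_matrix(
    genes,
    seed: int,
    tissues: tuple[str, ...] = TISSUES,
    focal_tissue: str = "CNS",
    p_focal: float = 0.3,
    p_nonfocal: float = 0.55,
):
    """Gene x tissue FPKM matrix with focal / non-focal / silent genes."""
    from .expression import ExpressionMatrix

    rng = _child_rng(seed, "fpkm")
    genes = sorted(set(genes))
    data = rng.uniform(0.0, 1.5, size=(len(genes), len(tissues)))
    others = [t for t in tissues if t != focal_tissue]
    for i in range(len(genes)):
        u = rng.random()
        if u < p_focal:
            j = tissues.index(focal_tissue)
        elif u < p_focal + p_nonfocal:
            j = tissues.index(others[int(rng.integers(len(others)))])
        else:
            continue  # not detected anywhere
        data[i, j] = rng.uniform(5.0, 100.0)
    frame = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=list(tissues))
    return ExpressionMatrix(frame, focal_tissue)


def simulate_states(fmap: FragmentMap, seed: int, mean_segment: int = 20_000) -> RegionSet:
    """Partition each chromosome into labelled chromatin-state segments."""
    rng = _child_rng(seed, "states")
    regions = []
    for chrom in fmap.chroms:
        clen = int(fmap.boundaries(chrom)[-1])
        pos = 0
        while pos < clen:
            seg = int(max(1000, rng.exponential(mean_segment)))
            end = min(pos + seg, clen)
            label = STATE_PALETTE[int(rng.integers(len(STATE_PALETTE)))]
            regions.append(Region(chrom, pos, end, label))
            pos = end
    return RegionSet("chromatin-states", regions, fmap.genome())


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimDataset:
    """Everything the pipeline consumes, plus the ground truth."""

    config: SimConfig
    seed: int
    sequences: dict[str, str]
    fmap: FragmentMap
    genes: list[GeneModel]
    truth: SimTruth
    replicates: list[tuple[CountTrack, CountTrack]]  # (fusion, control)
    states: RegionSet
    de_table: object  # DETable
    fpkm: object  # ExpressionMatrix
    bound_genes: set[str] = field(default_factory=set)


def simulate_dataset(
    config: SimConfig | None = None,
    seed: int = 1,
    target_bound_fraction: float = 0.75,
    n_up: int = 30,
    n_down: int = 30,
) -> SimDataset:
    """Generate a complete, internally consistent synthetic study.

    The DE table's "bound" pool is derived from the planted regions via
    the same 5 kb assignment rule the pipeline applies to called peaks,
    so recovered overlap fractions are directly comparable to the
    generating target.
    """
    from .annotate import assign_genes
    from .peaks import Peak, PeakSet

    cfg = config or SimConfig()
    seqs, fmap = simulate_genome(cfg, seed)
    genes = simulate_annotation(cfg, fmap, seed)
    truth = simulate_truth(cfg, fmap, seed)
    reps = simulate_damid(truth, fmap)
    states = simulate_states(fmap, seed)
    truth_peaks = PeakSet(
        [Peak(r.chrom, r.start, r.end, 2, float(r.score)) for r in truth.regions]
    )
    bound = {a.gene_id for a in assign_genes(truth_peaks, genes)}
    universe = {g.gene_id for g in genes}
    # n_de <= min(|bound|, |unbound|) keeps any binomial bound/unbound split feasible
    n_de_cap = max(2, min(len(bound), len(universe) - len(bound)))
    n_de = min(n_up + n_down, n_de_cap)
    n_up_eff = max(1, n_de // 2)
    n_down_eff = max(1, n_de - n_up_eff)
    de = simulate_de_table(bound, universe, target_bound_fraction, n_up_eff, n_down_eff, seed)
    fpkm = simulate_fpkm_matrix(sorted(universe), seed)
    return SimDataset(cfg, seed, seqs, fmap, genes, truth, reps, states, de, fpkm, bound)
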