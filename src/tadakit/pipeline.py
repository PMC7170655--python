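"""End-to-end orchestration of the TaDa analysis on a dataset.

Chains the whole pipeline: occupancy tracks per replicate, candidate
detection, shuffle-null FDR, significance filtering, replicate
intersection, gene assignment, feature classification, CATaDa
accessibility, metaprofiles, chromatin-state enrichment, and
expression integration.  Every output file starts with a header
comment recording the package version, the parameters and the seed
(never a timestamp, so repeated runs are byte-identical).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accessibility import (
    binding_accessibility_correlation,
    call_accessible_regions,
    metaprofile,
    state_enrichment,
)
from .annotate import assign_genes, assignments_to_frame, breakdown_to_frame, classify_features
from .config import PipelineConfig
from .expression import (
    bound_de_overlap_report,
    classify_de,
    overlap_report_text,
    tissue_of_origin,
)
from .genome import FragmentMap, write_bed, write_fasta, write_gff3
from .peaks import (
    PeakSet,
    call_candidate_peaks,
    estimate_fdr,
    filter_significant,
    intersect_replicates,
    peaks_to_bed,
    peaks_to_frame,
)
from .simulate import SimDataset
from .tracks import CountTrack, FragmentTrack, occupancy_ratio, replicate_concordance, rpm_normalize, write_bedgraph

log = logging.getLogger("tadakit")

__all__ = ["PipelineResult", "run_pipeline", "write_dataset", "counts_track_from_bedgraph"]


@dataclass
class PipelineResult:
    final_peaks: PeakSet
    significant: list[PeakSet]
    replicate_concordance: float
    bound_genes: set[str]
    binding_access_rho: float
    outputs: list[Path]


def _header(cfg: PipelineConfig, stage: str) -> str:
    return f"tadakit v{__version__} | {stage} | {cfg.header()}"


def counts_track_from_bedgraph(source, fmap: FragmentMap) -> CountTrack:
    """Read a raw-count bedGraph (one record per fragment) back into counts."""
    from .tracks import read_bedgraph

    track = read_bedgraph(source, fmap, units="counts")
    counts = np.rint(np.where(track.missing, 0.0, track.values)).astype(np.int64)
    return CountTrack(fmap, counts, max(int(counts.sum()), 1))


def write_dataset(ds: SimDataset, outdir: str | Path, cfg: PipelineConfig | None = None) -> list[Path]:
    """Write every pipeline input of a simulated dataset as plain text."""
    cfg = cfg or PipelineConfig(seed=ds.seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(name: str, text: str) -> Path:
        p = out / name
        p.write_text(text)
        written.append(p)
        return p

    _w("genome.fa", write_fasta(ds.sequences))
    _w("fragments.bed", ds.fmap.to_bed())
    _w("genes.gff3", write_gff3(ds.genes))
    _w("truth.bed", ds.truth.to_bed())
    _w("states.bed", write_bed(ds.states))
    for r, (fusion, control) in enumerate(ds.replicates, 1):
        for label, ct in (("fusion", fusion), ("control", control)):
            tr = FragmentTrack(ds.fmap, ct.counts.astype(float), np.zeros(ct.counts.size, bool), "counts")
            _w(f"rep{r}_{label}.counts.bedgraph", write_bedgraph(tr, header=_header(cfg, f"simulate rep{r} {label}")))
    _w("de_table.tsv", "# " + _header(cfg, "simulate DE") + "\n" + ds.de_table.frame.to_csv(sep="\t", index=False))
    _w("fpkm.tsv", "# " + _header(cfg, "simulate FPKM") + "\n" + ds.fpkm.frame.to_csv(sep="\t"))
    return written


def run_pipeline(ds: SimDataset, outdir: str | Path, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run every analysis stage on a dataset and write all result files."""
    cfg = cfg or PipelineConfig(seed=ds.seed)
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(name: str, text: str) -> Path:
        p = out / name
        p.write_text(text)
        written.append(p)
        return p

    def _wframe(name: str, frame: pd.DataFrame, stage: str, index: bool = False) -> Path:
        return _w(name, "# " + _header(cfg, stage) + "\n" + frame.to_csv(sep="\t", index=index))

    fmap = ds.fmap
    log.info("pipeline: %d chromosomes, %d GATC fragments", len(fmap.chroms), fmap.n_fragments)

    # 1. occupancy tracks and per-replicate peak calling
    ratio_tracks: list[FragmentTrack] = []
    significant: list[PeakSet] = []
    for r, (fusion, control) in enumerate(ds.replicates, 1):
        ratio = occupancy_ratio(fusion, control, cfg.pseudocount)
        ratio_tracks.append(ratio)
        _w(f"rep{r}_occupancy.bedgraph", write_bedgraph(ratio, header=_header(cfg, f"occupancy rep{r}")))
        candidates = call_candidate_peaks(ratio, cfg.occupancy_threshold, cfg.min_fragments)
        scored = estimate_fdr(
            candidates,
            ratio,
            n_shuffles=cfg.n_shuffles,
            seed=cfg.seed + r,
            occupancy_threshold=cfg.occupancy_threshold,
            min_fragments=cfg.min_fragments,
        )
        sig = filter_significant(scored, cfg.fdr_threshold, provenance={"replicate": r})
        significant.append(sig)
        log.info("rep%d: %d candidates, %d significant", r, len(candidates), len(sig))
        _wframe(f"rep{r}_significant_peaks.tsv", peaks_to_frame(sig), f"significant rep{r}")
        _w(f"rep{r}_significant_peaks.bed", peaks_to_bed(sig, header=_header(cfg, f"significant rep{r}")))

    # 2. replicate concordance and final peaks.  QC concordance is computed
    # on the RPM-normalised fusion tracks, which carry the shared binding and
    # accessibility structure; the ratio-track value is reported alongside.
    if len(ds.replicates) >= 2:
        rho_rep = replicate_concordance(
            rpm_normalize(ds.replicates[0][0]), rpm_normalize(ds.replicates[1][0])
        )
        rho_ratio = replicate_concordance(ratio_tracks[0], ratio_tracks[1])
    else:
        rho_rep = rho_ratio = float("nan")
    final = intersect_replicates(significant[0], significant[1], fmap) if len(significant) >= 2 else significant[0]
    log.info("final peaks: %d (replicate Spearman r=%.3f on RPM)", len(final), rho_rep)
    _w("final_peaks.bed", peaks_to_bed(final, header=_header(cfg, "final peaks")))
    _wframe("final_peaks.tsv", peaks_to_frame(final), "final peaks")

    # 3. gene assignment and feature classification
    assignments = assign_genes(final, ds.genes, cfg.max_distance)
    bound_genes = {a.gene_id for a in assignments}
    _wframe("peak_genes.tsv", assignments_to_frame(assignments), "peak-to-gene assignment")
    breakdown = classify_features(
        final, ds.genes, (cfg.promoter_upstream, cfg.promoter_downstream), cfg.tts_window
    )
    _wframe("feature_breakdown.tsv", breakdown_to_frame(breakdown), "feature classification")
    log.info("assignments: %d pairs, %d bound genes", len(assignments), len(bound_genes))

    # 4. CATaDa accessibility from the Dam-only control of replicate 1
    dam_rpm = rpm_normalize(ds.replicates[0][1])
    _w("accessibility_rpm.bedgraph", write_bedgraph(dam_rpm, header=_header(cfg, "CATaDa RPM")))
    accessible = call_accessible_regions(dam_rpm, cfg.accessibility_quantile, cfg.access_min_fragments)
    _w("accessible_regions.bed", write_bed(accessible))
    rho_access = binding_accessibility_correlation(ratio_tracks[0], dam_rpm)
    log.info("accessible regions: %d; binding-accessibility rho=%.3f", len(accessible), rho_access)

    if len(accessible) > 0:
        profile = metaprofile(ratio_tracks[0], accessible, cfg.open_flank, cfg.bin_width)
        _wframe("open_chromatin_profile_matrix.tsv", profile.to_frame(), "metaprofile matrix")
        _wframe("open_chromatin_profile_mean.tsv", profile.mean_frame(), "metaprofile mean")

    enr = state_enrichment(ratio_tracks[0], ds.states)
    _wframe("state_enrichment.tsv", enr.to_frame(), "chromatin-state enrichment")

    # 5. expression integration
    up, down = classify_de(ds.de_table, cfg.padj_cutoff, cfg.lfc_cutoff)
    universe = {g.gene_id for g in ds.genes}
    report = bound_de_overlap_report(bound_genes, up, down, universe)
    _w("bound_de_overlap.tsv", "# " + _header(cfg, "bound/DE overlap") + "\n" + overlap_report_text(report))
    tissue = tissue_of_origin(sorted(up), ds.fpkm, cfg.fpkm_threshold)
    tissue_frame = pd.DataFrame(
        {"gene_id": list(tissue.labels), "label": list(tissue.labels.values())}
    )
    _wframe("tissue_of_origin.tsv", tissue_frame, "tissue of origin (upregulated)")
    log.info("DE: %d up, %d down; bound fractions up=%.2f down=%.2f",
             len(up), len(down), report.up_bound_fraction, report.down_bound_fraction)

    summary = pd.DataFrame(
        {
            "quantity": [
                "n_fragments", "n_final_peaks", "n_bound_genes",
                "replicate_spearman_rpm", "replicate_spearman_ratio",
                "binding_accessibility_spearman",
                "up_bound_fraction", "down_bound_fraction",
            ],
            "value": [
                fmap.n_fragments, len(final), len(bound_genes),
                rho_rep, rho_ratio, rho_access,
                report.up_bound_fraction, report.down_bound_fraction,
            ],
        }
    )
    _wframe("summary.tsv", summary, "pipeline summary")

    return PipelineResult(final, significant, rho_rep, bound_genes, rho_access, written)
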