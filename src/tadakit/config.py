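"""Pipeline configuration: defaults, key=value files, overrides, validation.

Configuration is a flat key=value text file (``#`` comments allowed);
any key may also be overridden on the command line with
``--set key=value``.  Unknown keys are rejected, and every value is
checked against its documented domain before any stage runs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig", "load_config", "parse_overrides"]


@dataclass
class PipelineConfig:
    # occupancy-track construction
    pseudocount: float = 0.5  # RPM added to both samples before the log2 ratio
    # peak calling
    occupancy_threshold: float = 0.0  # log2 units; any fusion-over-control enrichment
    min_fragments: int = 2  # a peak needs >= 2 consecutive GATC fragments
    n_shuffles: int = 100
    fdr_threshold: float = 1e-4  # 0.01%, strict '<'
    # peak annotation
    max_distance: int = 5000  # bp, peak-to-gene assignment
    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    tts_window: int = 100
    # accessibility / profiles
    accessibility_quantile: float = 0.95
    access_min_fragments: int = 2
    crm_flank: int = 10000
    open_flank: int = 2000
    bin_width: int = 200
    # expression integration
    padj_cutoff: float = 0.05
    lfc_cutoff: float = 1.0
    fpkm_threshold: float = 2.0
    focal_tissue: str = "CNS"
    # randomness
    seed: int = 1

    def validate(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.min_fragments < 1:
            raise ValueError("min_fragments must be >= 1")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if not 0.0 < self.accessibility_quantile < 1.0:
            raise ValueError("accessibility_quantile must be in (0, 1)")
        if self.access_min_fragments < 1:
            raise ValueError("access_min_fragments must be >= 1")
        for key in ("crm_flank", "open_flank", "bin_width"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
        if self.crm_flank % self.bin_width or self.open_flank % self.bin_width:
            raise ValueError("flanks must be multiples of bin_width")
        if self.padj_cutoff <= 0 or self.lfc_cutoff <= 0 or self.fpkm_threshold < 0:
            raise ValueError("expression thresholds must be positive")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")

    def header(self) -> str:
        """Parameter record for output-file headers (no timestamps)."""
        parts = [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]
        return "; ".join(parts)


_FIELDS = {f.name: f.type for f in fields(PipelineConfig)}


def _coerce(key: str, raw: str):
    default = getattr(PipelineConfig(), key)
    if isinstance(default, bool):  # pragma: no cover - no bool keys today
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


def parse_overrides(pairs) -> dict:
    out = {}
    for pair in pairs:
        if "=" not in pair:
            raise ValueError(f"override {pair!r} is not of the form key=value")
        key, raw = pair.split("=", 1)
        key = key.strip()
        if key not in _FIELDS:
            raise ValueError(f"unknown configuration key {key!r}")
        out[key] = _coerce(key, raw.strip())
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    values: dict = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key=value, got {line!r}")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in _FIELDS:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            values[key] = _coerce(key, raw)
    values.update(overrides or {})
    cfg = PipelineConfig(**values)
    cfg.validate()
    return cfg
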