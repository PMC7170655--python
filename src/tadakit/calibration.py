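"""Null calibration of the shuffle-FDR peak caller.

On occupancy tracks with no planted binding, the empirical proportion
of candidate peaks classified significant at the pipeline's 0.01%
threshold should itself not exceed 0.01%.  This module runs that
simulation: i.i.d. Gaussian log2 values on a synthetic GATC grid,
candidate detection, shuffle-null FDR scoring, pooled over tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import FragmentMap
from .peaks import (
    DEFAULT_FDR_THRESHOLD,
    DEFAULT_MIN_FRAGMENTS,
    DEFAULT_N_SHUFFLES,
    DEFAULT_OCCUPANCY_THRESHOLD,
    call_candidate_peaks,
    estimate_fdr,
)
from .tracks import FragmentTrack

__all__ = ["CalibrationResult", "null_fdr_calibration"]


@dataclass
class CalibrationResult:
    n_tracks: int
    n_fragments: int
    n_candidates: int
    n_significant: int

    @property
    def proportion_significant(self) -> float:
        return self.n_significant / self.n_candidates if self.n_candidates else 0.0

    @property
    def percent_significant(self) -> float:
        return 100.0 * self.proportion_significant


def null_fdr_calibration(
    n_tracks: int = 200,
    n_fragments: int = 20_000,
    sd: float = 0.5,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 1,
    occupancy_threshold: float = DEFAULT_OCCUPANCY_THRESHOLD,
    min_fragments: int = DEFAULT_MIN_FRAGMENTS,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    fragment_length: int = 200,
) -> CalibrationResult:
    """Pool significance calls over pure-null tracks.

    Each track is ``n_fragments`` i.i.d. N(0, sd) log2 values on one
    chromosome; candidates and FDRs use the production parameters.
    All per-track randomness derives from the single master seed.
    """
    fmap = FragmentMap({"chrN": np.arange(n_fragments + 1, dtype=np.int64) * fragment_length})
    missing = np.zeros(n_fragments, dtype=bool)
    master = np.random.default_rng(seed)
    track_seeds = master.integers(0, 2**31 - 1, size=(n_tracks, 2))

    n_candidates = n_significant = 0
    for t in range(n_tracks):
        values = np.random.default_rng(int(track_seeds[t, 0])).normal(0.0, sd, size=n_fragments)
        track = FragmentTrack(fmap, values, missing, units="log2")
        candidates = call_candidate_peaks(track, occupancy_threshold, min_fragments)
        scored = estimate_fdr(
            candidates,
            track,
            n_shuffles=n_shuffles,
            seed=int(track_seeds[t, 1]),
            occupancy_threshold=occupancy_threshold,
            min_fragments=min_fragments,
        )
        n_candidates += len(scored)
        n_significant += sum(1 for p in scored if p.fdr < fdr_threshold)
    return CalibrationResult(n_tracks, n_fragments, n_candidates, n_significant)
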