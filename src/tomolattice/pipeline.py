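"""End-to-end convenience wrapper: pairs -> theta -> classes -> chains.

Thin glue over :mod:`pair_analysis` and :mod:`oligomer_chains` so the CLI,
tests and scripts all run the identical sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .models import Chain, CoverageStats, FilamentPath, PairRecord, Particle
from .oligomer_chains import chain_length_histogram, coverage_stats, group_chains
from .pair_analysis import attach_theta, classify_pair, find_neighbor_pairs, theta_histogram

__all__ = ["AnalysisResult", "analyze_decoration"]


@dataclass
class AnalysisResult:
    pairs: List[PairRecord]
    selected_pairs: List[PairRecord]  # perpendicular class
    chains: List[Chain]
    chain_histogram: Dict[int, int]
    theta_counts: np.ndarray
    theta_edges: np.ndarray
    theta_mode: float
    coverage: List[CoverageStats]
    coverage_totals: CoverageStats


def analyze_decoration(
    particles: Sequence[Particle],
    paths: Sequence[FilamentPath],
    d_min: float = 5.0,
    d_max: float = 12.0,
    perpendicular_band: float = 30.0,
    parallel_band: float = 30.0,
    bin_width: float = 5.0,
    center_histogram_on: Optional[float] = None,
    include_singletons: bool = True,
) -> AnalysisResult:
    """Run the full geometric analysis on an already-cleaned particle set."""
    pairs = find_neighbor_pairs(particles, d_min=d_min, d_max=d_max)
    attach_theta(pairs, particles, paths)
    for pair in pairs:
        classify_pair(pair, perpendicular_band, parallel_band)
    selected = [p for p in pairs if p.pair_class == "perpendicular"]
    chains = group_chains(selected, particles, include_singletons=include_singletons)
    hist = chain_length_histogram(chains)
    if pairs:
        counts, edges, mode = theta_histogram(
            pairs, bin_width=bin_width, center_on=center_histogram_on
        )
    else:
        counts, edges, mode = np.array([]), np.array([]), float("nan")
    per_fil, totals = coverage_stats(particles, paths)
    return AnalysisResult(
        pairs=pairs,
        selected_pairs=selected,
        chains=chains,
        chain_histogram=hist,
        theta_counts=counts,
        theta_edges=edges,
        theta_mode=mode,
        coverage=per_fil,
        coverage_totals=totals,
    )
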