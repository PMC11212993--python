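"""Chain grouping of selected pairs and decoration-coverage statistics.

Perpendicular-class pairs sharing a particle are merged into chains
(connected components); a chain's size in dimers is the oligomer-length
statistic. Particles that appear in no selected pair count as singleton
chains by default, since isolated dimers are themselves a reported
species.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Dict, List, Sequence, Tuple

import networkx as nx

from .models import Chain, CoverageStats, FilamentPath, PairRecord, Particle

log = logging.getLogger(__name__)

__all__ = ["group_chains", "chain_length_histogram", "coverage_stats"]


def group_chains(
    selected_pairs: Sequence[PairRecord],
    all_particles: Sequence[Particle],
    include_singletons: bool = True,
) -> List[Chain]:
    """Connected components of the particle graph with pair edges.

    Vertices are particles, edges the selected pairs; particles touched by
    no pair become size-1 chains when ``include_singletons`` is on. Chains
    partition the particle set. Branching particles (>2 edges) stay in one
    component. Output is ordered by smallest member id.
    """
    by_id = {p.particle_id: p for p in all_particles}
    g = nx.Graph()
    for pair in selected_pairs:
        for pid in (pair.id_a, pair.id_b):
            if pid not in by_id:
                raise ValueError(f"pair references unknown particle {pid}")
        g.add_edge(pair.id_a, pair.id_b)
    if include_singletons:
        g.add_nodes_from(by_id)
    components = sorted(nx.connected_components(g), key=min)
    chains = [
        Chain(
            chain_id=i,
            filament_id=by_id[min(comp)].filament_id,
            member_particle_ids=frozenset(comp),
        )
        for i, comp in enumerate(components)
    ]
    log.info(
        "group_chains: %d pairs + %d particles -> %d chains",
        len(selected_pairs),
        len(all_particles),
        len(chains),
    )
    return chains


def chain_length_histogram(chains: Sequence[Chain]) -> Dict[int, int]:
    """Map chain size (dimer count) -> number of chains of that size."""
    return dict(sorted(Counter(c.size for c in chains).items()))


def coverage_stats(
    particles: Sequence[Particle],
    paths: Sequence[FilamentPath],
    unit: float = 1.0,
) -> Tuple[List[CoverageStats], CoverageStats]:
    """Decoration density per filament and in aggregate.

    Density is particles per ``unit`` nm of traced filament length
    (default 1 nm, matching the per-nm bookkeeping of sparse decoration).
    Returns (per-filament list, dataset totals).
    """
    by_fil = {p.filament_id: p for p in paths}
    counts: Counter = Counter()
    for p in particles:
        if p.filament_id not in by_fil:
            raise ValueError(
                f"particle {p.particle_id} on untraced filament {p.filament_id!r}"
            )
        counts[p.filament_id] += 1
    per_fil = []
    for fil_id, path in sorted(by_fil.items()):
        length = path.length
        if length <= 0:
            raise ValueError(f"filament {fil_id} has nonpositive length")
        n = counts.get(fil_id, 0)
        per_fil.append(
            CoverageStats(
                filament_id=fil_id,
                particle_count=n,
                filament_length=length,
                particles_per_nm=n * unit / length,
            )
        )
    total_len = sum(s.filament_length for s in per_fil)
    total_n = sum(s.particle_count for s in per_fil)
    totals = CoverageStats(
        filament_id="__all__",
        particle_count=total_n,
        filament_length=total_len,
        particles_per_nm=(total_n * unit / total_len) if total_len > 0 else 0.0,
    )
    return per_fil, totals
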