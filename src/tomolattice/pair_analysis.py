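"""Pairwise statistics: neighbor pairs, the helical angle theta, classes.

The helical angle theta of a pair is the angle between the 3-D
displacement vector joining the two particles (lower id to higher id) and
the unit tangent of the filament node nearest the pair midpoint. Because
microtubule polarity is unknown per filament, theta is reported on the
full [0, 180] degree range rather than folded to [0, 90]: ~90 deg means a
ring-like oligomer wrapping the tube, ~33 deg (or its 147 deg mirror) the
active-like right-handed filament geometry.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .geometry_core import angle_between_deg
from .models import FilamentPath, PairRecord, Particle

log = logging.getLogger(__name__)

__all__ = [
    "find_neighbor_pairs",
    "compute_theta",
    "attach_theta",
    "classify_pair",
    "theta_histogram",
]

DEFAULT_D_MIN = 5.0
DEFAULT_D_MAX = 12.0


def find_neighbor_pairs(
    particles: Sequence[Particle],
    d_min: float = DEFAULT_D_MIN,
    d_max: float = DEFAULT_D_MAX,
) -> List[PairRecord]:
    """All unordered same-filament pairs with d_min <= distance <= d_max.

    Each qualifying pair appears exactly once with id_a < id_b. The
    default [5, 12] nm window brackets the ~8 nm picking pitch.
    """
    if not 0 < d_min < d_max:
        raise ValueError("require 0 < d_min < d_max")
    by_fil: Dict[Tuple[str, str], List[Particle]] = {}
    for p in particles:
        if p.filament_id is None or p.tomogram_id is None:
            raise ValueError(f"particle {p.particle_id} lacks filament assignment")
        by_fil.setdefault((p.tomogram_id, p.filament_id), []).append(p)

    records: List[PairRecord] = []
    for (_, fil_id), group in sorted(by_fil.items()):
        group = sorted(group, key=lambda p: p.particle_id)
        pos = np.array([p.position for p in group])
        tree = cKDTree(pos)
        for i, j in sorted(tree.query_pairs(d_max)):
            a, b = group[i], group[j]
            if a.particle_id > b.particle_id:
                a, b = b, a
            disp = b.position - a.position
            d = float(np.linalg.norm(disp))
            if d_min <= d <= d_max:
                records.append(
                    PairRecord(
                        id_a=a.particle_id,
                        id_b=b.particle_id,
                        filament_id=fil_id,
                        distance=d,
                        displacement=disp,
                    )
                )
    records.sort(key=lambda r: (r.id_a, r.id_b))
    log.info(
        "find_neighbor_pairs: %d particles -> %d pairs in [%.3g, %.3g] nm",
        len(particles),
        len(records),
        d_min,
        d_max,
    )
    return records


def compute_theta(pair: PairRecord, tangent_at_midpoint: np.ndarray) -> float:
    """Helical angle between the pair displacement and the local tangent.

    Not folded to [0, 90]: filament polarity is unknown, so the sign of
    the tangent is arbitrary and theta spans the full [0, 180] range.
    """
    if np.linalg.norm(pair.displacement) == 0:
        raise ValueError("zero displacement has no direction")
    return angle_between_deg(pair.displacement, tangent_at_midpoint)


def _tangent_near(path: FilamentPath, point: np.ndarray) -> np.ndarray:
    if path.nodes is None or path.tangents is None:
        raise ValueError(f"path {path.filament_id} is not resampled")
    i = int(np.argmin(np.linalg.norm(path.nodes - point, axis=1)))
    return path.tangents[i]


def attach_theta(
    pairs: Sequence[PairRecord],
    particles: Sequence[Particle],
    paths: Sequence[FilamentPath],
) -> List[PairRecord]:
    """Fill in theta for each pair from the tangent nearest its midpoint."""
    by_id = {p.particle_id: p for p in particles}
    path_by_fil: Dict[str, FilamentPath] = {}
    for path in paths:
        path_by_fil[path.filament_id] = path
    for pair in pairs:
        a = by_id[pair.id_a]
        mid = a.position + 0.5 * pair.displacement
        tangent = _tangent_near(path_by_fil[pair.filament_id], mid)
        pair.theta = compute_theta(pair, tangent)
    return list(pairs)


def classify_pair(
    pair: PairRecord,
    perpendicular_band: float = 30.0,
    parallel_band: float = 30.0,
) -> str:
    """Class label: perpendicular (|theta-90| <= band), parallel (theta
    within band of 0 or 180), else other."""
    if perpendicular_band + parallel_band > 90.0:
        raise ValueError("bands overlap: perpendicular_band + parallel_band > 90")
    if pair.theta is None:
        raise ValueError("theta not computed for pair")
    th = pair.theta
    if abs(th - 90.0) <= perpendicular_band:
        cls = "perpendicular"
    elif th <= parallel_band or th >= 180.0 - parallel_band:
        cls = "parallel"
    else:
        cls = "other"
    pair.pair_class = cls
    return cls


def theta_histogram(
    pairs: Sequence[PairRecord],
    bin_width: float = 5.0,
    center_on: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Histogram of theta over [0, 180] and the modal bin centre.

    Bins are aligned so that bin centres fall on multiples of
    ``bin_width`` (0, 5, 10, ... by default); pass ``center_on`` to align
    one bin centre on a specific angle instead (e.g. a planted 33 deg).
    Returns (counts, bin_edges, modal_bin_center); ties break toward the
    lower bin.

    The edge bins extend half a bin width past 0 and 180 so the closed
    range is fully covered and counts sum to the number of pairs.
    """
    thetas = np.array([p.theta for p in pairs], dtype=float)
    if thetas.size == 0:
        raise ValueError("no pairs with theta to histogram")
    anchor = 0.0 if center_on is None else float(center_on)
    lo = anchor - bin_width * (np.ceil((anchor + bin_width / 2) / bin_width))
    start = lo + bin_width / 2  # first edge; bin centres at anchor + k*width
    edges = np.arange(start, 180.0 + bin_width, bin_width)
    while edges[0] > 0.0:
        edges = np.concatenate([[edges[0] - bin_width], edges])
    while edges[-1] < 180.0:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(thetas, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = float(centers[int(np.argmax(counts))])
    return counts, edges, mode
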