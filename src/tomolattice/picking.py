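"""Cylindrical picking-grid generation and particle-cleaning filters.

The picking strategy oversamples the filament surface: rings of candidate
positions orthogonal to the traced path, pointing outwards, at 23 nm
radius, 7 nm ring spacing and 18 subunits per ring by default. Cleaning
consists of azimuth randomization (missing-wedge mitigation), greedy
distance-based duplicate removal, and a cross-correlation cutoff
(keep >= 0.32).
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry_core import build_local_frames, tangents_central_diff
from .models import FilamentPath, Particle, PickGridSpec

log = logging.getLogger(__name__)

__all__ = [
    "resample_path",
    "generate_ring_grid",
    "randomize_azimuth",
    "remove_duplicates",
    "filter_by_cc",
]


def resample_path(
    control_points: np.ndarray,
    spacing: float,
    tomogram_id: str = "tomo",
    filament_id: str = "fil",
) -> FilamentPath:
    """Resample a polyline equidistantly by arc length.

    Nodes sit on the piecewise-linear interpolant at arc lengths
    0, spacing, 2*spacing, ...; both endpoints are retained, so the last
    gap may be shorter than ``spacing``. If ``spacing`` exceeds the total
    length only the two endpoints are returned.
    """
    pts = np.asarray(control_points, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValueError("need >= 2 control points to resample")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise ValueError("path has zero length")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(0.0, total, spacing)
    if total - targets[-1] > 1e-12:
        targets = np.append(targets, total)
    # locate each target arc length on its segment
    idx = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    nodes = pts[idx] + frac[:, None] * (pts[idx + 1] - pts[idx])
    path = FilamentPath(
        tomogram_id=tomogram_id,
        filament_id=filament_id,
        control_points=pts,
        nodes=nodes,
        spacing=spacing,
    )
    path.tangents = tangents_central_diff(nodes)
    return path


def generate_ring_grid(path: FilamentPath, spec: PickGridSpec) -> List[Particle]:
    """One ring of evenly spaced outward-pointing particles per path node.

    Each particle sits at ``spec.radius`` from its node in the node's
    normal plane. Orientations place local +z along the outward radial
    direction and local +y along the path tangent (local +x = y cross z
    completes the right-handed frame).
    """
    if path.nodes is None or path.spacing is None:
        raise ValueError("path must be resampled before grid generation")
    if abs(path.spacing - spec.ring_spacing) > 1e-9:
        raise ValueError(
            f"path resampled at {path.spacing} nm but grid expects "
            f"{spec.ring_spacing} nm ring spacing"
        )
    frames = build_local_frames(path)
    k = spec.subunits_per_ring
    az = np.radians(360.0 * np.arange(k) / k)
    particles: List[Particle] = []
    pid = 0
    for ring_index, (node, (t, n, b)) in enumerate(zip(path.nodes, frames)):
        outward = np.cos(az)[:, None] * n + np.sin(az)[:, None] * b
        for j in range(k):
            z_axis = outward[j]
            y_axis = t
            x_axis = np.cross(y_axis, z_axis)
            particles.append(
                Particle(
                    particle_id=pid,
                    tomogram_id=path.tomogram_id,
                    filament_id=path.filament_id,
                    position=node + spec.radius * z_axis,
                    orientation=np.column_stack([x_axis, y_axis, z_axis]),
                    ring_index=ring_index,
                    azimuth_index=j,
                )
            )
            pid += 1
    return particles


def randomize_azimuth(particles: Sequence[Particle], seed: int) -> List[Particle]:
    """Spin each particle about its own outward axis by a uniform angle.

    Positions are untouched; each orientation is post-multiplied by a
    rotation about local +z (the outward axis) with angle uniform on
    [0, 360). Deterministic for a fixed seed. This decorrelates initial
    in-plane orientations so the missing wedge does not bias alignment.
    """
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0.0, 360.0, size=len(particles))
    out = []
    for p, a in zip(particles, angles):
        spin = Rotation.from_euler("z", a, degrees=True).as_matrix()
        out.append(p.copy(orientation=p.orientation @ spin))
    return out


def remove_duplicates(
    particles: Sequence[Particle], min_distance: float = 4.0
) -> List[Particle]:
    """Greedy duplicate removal by ascending particle id.

    A particle is dropped if it lies within ``min_distance`` of any
    already-kept particle; the survivors' minimum pairwise distance is
    therefore >= ``min_distance``. Idempotent.
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be positive")
    if not particles:
        return []
    ordered = sorted(particles, key=lambda p: p.particle_id)
    kept: List[Particle] = []
    kept_pos: List[np.ndarray] = []
    tree: Optional[cKDTree] = None
    rebuild_every = 256
    pending: List[np.ndarray] = []
    for p in ordered:
        ok = True
        if tree is not None:
            d, _ = tree.query(p.position, k=1)
            if d < min_distance:
                ok = False
        if ok and pending:
            d2 = np.linalg.norm(np.asarray(pending) - p.position, axis=1)
            if d2.min() < min_distance:
                ok = False
        if ok:
            kept.append(p)
            kept_pos.append(p.position)
            pending.append(p.position)
            if len(pending) >= rebuild_every:
                tree = cKDTree(np.asarray(kept_pos))
                pending = []
    log.info("remove_duplicates: %d -> %d particles", len(particles), len(kept))
    return kept


def filter_by_cc(
    particles: Sequence[Particle], threshold: float = 0.32
) -> List[Particle]:
    """Keep particles with cc_score >= threshold (order preserved).

    The boundary is inclusive: particles *lower than* the threshold are
    removed.
    """
    for p in particles:
        if p.cc_score is None:
            raise ValueError(f"particle {p.particle_id} has no cc_score")
    kept = [p for p in particles if p.cc_score >= threshold]
    log.info(
        "filter_by_cc(threshold=%.3g): %d -> %d particles",
        threshold,
        len(particles),
        len(kept),
    )
    return kept


def apply_polarity_flips(
    particles: Sequence[Particle], flipped_filaments: Iterable[str]
) -> List[Particle]:
    """Apply a per-filament 180-degree flip about the outward axis.

    Stands in for the manual step of flipping subtomograms whose tubulin
    skew runs opposite to the reference; detection from density is out of
    scope, so flips are declared per filament id.
    """
    flip_set = set(flipped_filaments)
    flip = Rotation.from_euler("z", 180.0, degrees=True).as_matrix()
    out = []
    for p in particles:
        if p.filament_id in flip_set:
            out.append(p.copy(orientation=p.orientation @ flip))
        else:
            out.append(p.copy())
    return out
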