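"""Neighbor-pair enumeration, the theta angle, classes and histograms."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tomolattice import (
    DecorationSpec,
    classify_pair,
    compute_theta,
    find_neighbor_pairs,
    make_synthetic_dataset,
    theta_histogram,
)
from tomolattice.models import FilamentPath, PairRecord, Particle
from tomolattice.pair_analysis import attach_theta


def _particles(positions, filament="f"):
    return [
        Particle(i, "t", filament, np.asarray(p, float), np.eye(3))
        for i, p in enumerate(positions)
    ]


def _pair(a=np.zeros(3), b=np.array([1.0, 0, 0]), ids=(0, 1)):
    return PairRecord(
        id_a=ids[0],
        id_b=ids[1],
        filament_id="f",
        distance=float(np.linalg.norm(b - a)),
        displacement=b - a,
    )


# ------------------------------------------------------------------- pairs

def test_collinear_particles_give_expected_pairs():
    parts = _particles([[0, 0, 0], [0, 0, 8], [0, 0, 16]])
    pairs = find_neighbor_pairs(parts, 5, 12)
    assert [(p.id_a, p.id_b) for p in pairs] == [(0, 1), (1, 2)]
    far = _particles([[0, 0, 0], [0, 0, 20], [0, 0, 40]])
    assert find_neighbor_pairs(far, 5, 12) == []


def test_pairs_respect_filament_boundaries():
    a = _particles([[0, 0, 0], [0, 0, 8]], filament="f1")
    b = [
        Particle(10, "t", "f2", np.array([0.0, 8.0, 0.0]), np.eye(3)),
    ]
    pairs = find_neighbor_pairs(a + b, 5, 12)
    assert [(p.id_a, p.id_b) for p in pairs] == [(0, 1)]  # no cross-filament pair


def test_pair_enumeration_matches_brute_force(rng):
    for n in (50, 200, 500):
        parts = _particles(rng.uniform(0, 60, size=(n, 3)))
        got = {(p.id_a, p.id_b) for p in find_neighbor_pairs(parts, 5, 12)}
        want = set()
        for a, b in itertools.combinations(parts, 2):
            d = np.linalg.norm(a.position - b.position)
            if 5 <= d <= 12:
                want.add((a.particle_id, b.particle_id))
        assert got == want


def test_invalid_window_rejected():
    with pytest.raises(ValueError):
        find_neighbor_pairs([], 12, 5)


# ------------------------------------------------------------------- theta

def test_theta_perpendicular_and_parallel_displacements():
    t = np.array([0.0, 0.0, 1.0])
    assert compute_theta(_pair(b=np.array([1.0, 0, 0])), t) == pytest.approx(90.0)
    assert compute_theta(_pair(b=np.array([0, 0, 3.0])), t) == pytest.approx(0.0)
    assert compute_theta(_pair(b=np.array([0, 0, -3.0])), t) == pytest.approx(180.0)


def test_theta_spans_full_range_on_random_pairs(rng):
    thetas = []
    for _ in range(10000):
        disp = rng.normal(size=3)
        tangent = rng.normal(size=3)
        thetas.append(compute_theta(_pair(b=disp), tangent))
    thetas = np.array(thetas)
    assert np.all((thetas >= 0) & (thetas <= 180))
    assert thetas.max() > 170 and thetas.min() < 10  # unfolded: both ends reached


def test_theta_invariant_under_global_rigid_rotation(ring_dataset):
    rot = Rotation.from_euler("zyx", [31, -47, 13], degrees=True).as_matrix()
    parts = ring_dataset.particles
    paths = ring_dataset.paths
    pairs0 = attach_theta(find_neighbor_pairs(parts, 5, 12), parts, paths)
    rparts = [
        p.copy(position=rot @ p.position, orientation=rot @ p.orientation)
        for p in parts
    ]
    rpaths = []
    for path in paths:
        rpaths.append(
            FilamentPath(
                path.tomogram_id,
                path.filament_id,
                (rot @ path.control_points.T).T,
                nodes=(rot @ path.nodes.T).T,
                tangents=(rot @ path.tangents.T).T,
                spacing=path.spacing,
            )
        )
    pairs1 = attach_theta(find_neighbor_pairs(rparts, 5, 12), rparts, rpaths)
    assert len(pairs0) == len(pairs1) > 50
    for p0, p1 in zip(pairs0, pairs1):
        assert (p0.id_a, p0.id_b) == (p1.id_a, p1.id_b)
        assert p0.theta == pytest.approx(p1.theta, abs=1e-8)


def test_swapping_pair_order_mirrors_theta():
    t = np.array([0.0, 0.0, 1.0])
    disp = np.array([1.0, 2.0, 3.0])
    fwd = compute_theta(_pair(b=disp), t)
    rev = compute_theta(_pair(b=-disp), t)
    assert fwd + rev == pytest.approx(180.0)


# ------------------------------------------------------------------ classes

def test_pair_classification_bands():
    t = np.array([0.0, 0.0, 1.0])
    for disp, expect in [
        (np.array([1.0, 0, 0]), "perpendicular"),  # theta 90
        (np.array([0.1, 0, 1.0]), "parallel"),  # theta ~5.7
        (np.array([1.0, 0, 1.0]), "other"),  # theta 45, outside both bands
    ]:
        pair = _pair(b=disp)
        pair.theta = compute_theta(pair, t)
        assert classify_pair(pair) == expect


def test_classification_rejects_overlapping_bands():
    pair = _pair()
    pair.theta = 50.0
    with pytest.raises(ValueError):
        classify_pair(pair, perpendicular_band=50, parallel_band=50)
    bare = _pair()
    with pytest.raises(ValueError):
        classify_pair(bare)


# ---------------------------------------------------------------- histogram

def _records_with_thetas(thetas):
    out = []
    for i, th in enumerate(thetas):
        r = _pair(ids=(2 * i, 2 * i + 1))
        r.theta = float(th)
        out.append(r)
    return out


def test_histogram_counts_conserved_and_mode_tie_breaks_low(rng):
    recs = _records_with_thetas(rng.uniform(0, 180, size=500))
    counts, edges, _ = theta_histogram(recs)
    assert counts.sum() == 500
    assert edges[0] <= 0.0 and edges[-1] >= 180.0
    # two equally filled bins: mode reports the lower bin centre
    recs = _records_with_thetas([10.0, 10.1, 30.0, 30.1])
    _, _, mode = theta_histogram(recs)
    assert mode == 10.0
    with pytest.raises(ValueError):
        theta_histogram([])


def test_ring_dataset_histogram_peaks_at_90():
    ds = make_synthetic_dataset(
        10, DecorationSpec(mode="ring", occupancy=0.3, ang_noise_sigma=5.0), seed=3
    )
    pairs = attach_theta(find_neighbor_pairs(ds.particles, 5, 12), ds.particles, ds.paths)
    _, _, mode = theta_histogram(pairs)
    assert mode == 90.0


def test_helix_dataset_histogram_peaks_at_33():
    ds = make_synthetic_dataset(
        10, DecorationSpec(mode="helix", occupancy=0.3, ang_noise_sigma=5.0), seed=3
    )
    pairs = attach_theta(find_neighbor_pairs(ds.particles, 5, 12), ds.particles, ds.paths)
    counts, edges, mode = theta_histogram(pairs, center_on=33.0)
    assert mode == pytest.approx(33.0)
    # 33 deg sits on a default-grid bin edge, so that mode is within one bin
    _, edges0, mode0 = theta_histogram(pairs)
    assert abs(mode0 - 33.0) <= 5.0
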