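"""Synthetic lattice/decoration generator against its planted ground truth."""

import numpy as np
import pytest

from tomolattice import (
    DecorationSpec,
    LatticeSpec,
    angle_between_deg,
    decorate_filament,
    make_microtubule_lattice,
    make_synthetic_dataset,
    perturb_particles,
    resample_path,
)


# ------------------------------------------------------------------- lattice

def test_13pf_lattice_twist_rounds_to_printed_value():
    subunits, _ = make_microtubule_lattice(LatticeSpec(n_protofilaments=13))
    az = np.degrees(np.unwrap(np.arctan2(subunits[:, 1], subunits[:, 0])))
    mean_inc = np.mean(np.abs(np.diff(az)))
    assert mean_inc == pytest.approx(360.0 / 13.0, abs=1e-9)
    assert round(mean_inc, 1) == 27.7


def test_lattice_radius_and_subunit_count():
    spec = LatticeSpec(tube_diameter=30.0, length=100.0, subunit_rise=0.94)
    subunits, axis = make_microtubule_lattice(spec)
    assert np.allclose(np.linalg.norm(subunits[:, :2], axis=1), 15.0)
    assert len(subunits) == int(np.floor(100.0 / 0.94)) + 1
    assert axis.length == pytest.approx(100.0)


def test_lattice_rise_between_consecutive_subunits():
    subunits, _ = make_microtubule_lattice(LatticeSpec(length=50.0))
    assert np.allclose(np.diff(subunits[:, 2]), 0.94)


# ---------------------------------------------------------------- decoration

def _within_chain_step_angles(particles, path):
    """Angles between consecutive within-chain displacements and the tangent."""
    by_chain = {}
    for p in particles:
        by_chain.setdefault(p.truth_chain_id, []).append(p)
    angles, lengths = [], []
    for members in by_chain.values():
        members = sorted(members, key=lambda p: p.particle_id)
        for a, b in zip(members[:-1], members[1:]):
            disp = b.position - a.position
            i = int(np.argmin(np.linalg.norm(path.nodes - a.position, axis=1)))
            angles.append(angle_between_deg(disp, path.tangents[i]))
            lengths.append(np.linalg.norm(disp))
    return np.array(angles), np.array(lengths)


@pytest.mark.parametrize(
    "mode,theta", [("ring", 90.0), ("helix", 33.0)]
)
def test_noiseless_decoration_places_steps_at_target_angle(mode, theta):
    path = resample_path(np.array([[0, 0, 0], [0, 0, 400.0]]), 7.0)
    spec = DecorationSpec(mode=mode, occupancy=0.5, seed=3)
    particles = decorate_filament(path, spec)
    assert len(particles) > 20
    angles, lengths = _within_chain_step_angles(particles, path)
    assert np.allclose(angles, theta, atol=1e-6)
    assert np.allclose(lengths, spec.neighbor_spacing, atol=1e-6)


def test_helix_mode_is_right_handed():
    path = resample_path(np.array([[0, 0, 0], [0, 0, 400.0]]), 7.0)
    particles = decorate_filament(path, DecorationSpec(mode="helix", occupancy=0.5, seed=3))
    by_chain = {}
    for p in particles:
        by_chain.setdefault(p.truth_chain_id, []).append(p)
    checked = 0
    for members in by_chain.values():
        members = sorted(members, key=lambda p: p.particle_id)
        for a, b in zip(members[:-1], members[1:]):
            dz = b.position[2] - a.position[2]
            dphi = np.arctan2(b.position[1], b.position[0]) - np.arctan2(
                a.position[1], a.position[0]
            )
            dphi = (dphi + np.pi) % (2 * np.pi) - np.pi
            assert dz > 0 and dphi > 0  # azimuth grows with height
            checked += 1
    assert checked > 10


def test_concentrated_chain_length_distribution_recovers_exactly():
    path = resample_path(np.array([[0, 0, 0], [0, 0, 600.0]]), 7.0)
    spec = DecorationSpec(
        mode="ring", occupancy=0.3, chain_length_distribution={3: 1.0}, seed=11
    )
    particles = decorate_filament(path, spec)
    sizes = {}
    for p in particles:
        sizes[p.truth_chain_id] = sizes.get(p.truth_chain_id, 0) + 1
    assert len(sizes) > 5
    assert set(sizes.values()) == {3}


def test_chains_never_share_particles_and_stay_separated():
    path = resample_path(np.array([[0, 0, 0], [0, 0, 500.0]]), 7.0)
    spec = DecorationSpec(mode="ring", occupancy=0.6, seed=5)
    particles = decorate_filament(path, spec)
    assert all(p.truth_chain_id is not None for p in particles)
    ids = [p.particle_id for p in particles]
    assert len(ids) == len(set(ids))
    pos = np.array([p.position for p in particles])
    chain = np.array([p.truth_chain_id for p in particles])
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    cross = chain[:, None] != chain[None, :]
    assert d[cross].min() >= spec.min_chain_separation - 1e-9


def test_particles_lie_on_binding_cylinder():
    path = resample_path(np.array([[0, 0, 0], [0, 0, 300.0]]), 7.0)
    particles = decorate_filament(path, DecorationSpec(mode="ring", occupancy=0.4, seed=1))
    r = np.linalg.norm(np.array([p.position for p in particles])[:, :2], axis=1)
    assert np.allclose(r, 23.0, atol=1e-9)


# -------------------------------------------------------------------- noise

def test_perturb_sigma_zero_is_identity(ring_dataset):
    out = perturb_particles(ring_dataset.particles, 0.0, 0.0, seed=1)
    for a, b in zip(out, ring_dataset.particles):
        assert np.array_equal(a.position, b.position)
        assert np.array_equal(a.orientation, b.orientation)


def test_perturb_rms_displacement_matches_chi_expectation(rng):
    from tomolattice.models import Particle

    parts = [
        Particle(i, "t", "f", rng.uniform(0, 100, 3), np.eye(3)) for i in range(10000)
    ]
    out = perturb_particles(parts, pos_noise_sigma=1.0, ang_noise_sigma=0.0, seed=4)
    disp = np.array([a.position - b.position for a, b in zip(out, parts)])
    rms = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    assert rms == pytest.approx(np.sqrt(3.0), rel=0.05)


def test_perturb_is_deterministic(ring_dataset):
    a = perturb_particles(ring_dataset.particles, 1.0, 5.0, seed=8)
    b = perturb_particles(ring_dataset.particles, 1.0, 5.0, seed=8)
    for x, y in zip(a, b):
        assert np.array_equal(x.position, y.position)
        assert np.array_equal(x.orientation, y.orientation)
    with pytest.raises(ValueError):
        perturb_particles(ring_dataset.particles, -1.0, 0.0, seed=1)


# ------------------------------------------------------------------ dataset

def test_dataset_truth_histogram_matches_recount(ring_dataset):
    truth = ring_dataset.truth
    planted = truth[truth.truth_chain_id >= 0]
    by_chain = planted.groupby("truth_chain_id").size()
    recount = {}
    for p in ring_dataset.particles:
        if p.truth_chain_id >= 0:
            recount[p.truth_chain_id] = recount.get(p.truth_chain_id, 0) + 1
    assert by_chain.to_dict() == recount


def test_dataset_deterministic_per_seed():
    spec = DecorationSpec(mode="ring", occupancy=0.3)
    a = make_synthetic_dataset(3, spec, seed=5)
    b = make_synthetic_dataset(3, spec, seed=5)
    assert len(a.particles) == len(b.particles)
    for x, y in zip(a.particles, b.particles):
        assert np.array_equal(x.position, y.position)


def test_decoys_get_low_scores_and_no_truth_chain():
    ds = make_synthetic_dataset(
        3, DecorationSpec(mode="ring", occupancy=0.3), seed=2, n_decoys_per_filament=10
    )
    decoys = [p for p in ds.particles if p.truth_chain_id == -1]
    planted = [p for p in ds.particles if p.truth_chain_id >= 0]
    assert len(decoys) == 30
    assert np.mean([p.cc_score for p in decoys]) < np.mean([p.cc_score for p in planted])
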