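"""Domain containers shared by all pipeline stages.

Positions are always in nanometres and orientations are 3x3 proper rotation
matrices once inside the library; unit conversion happens only in
:mod:`tomolattice.io_tables`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Particle",
    "FilamentPath",
    "PairRecord",
    "Chain",
    "CoverageStats",
    "PickGridSpec",
    "LatticeSpec",
    "DecorationSpec",
]


@dataclass
class Particle:
    """One subtomogram reduced to its pose record.

    Attributes
    ----------
    particle_id : int
        Unique within a dataset.
    tomogram_id, filament_id : str
        Which tomogram / traced microtubule the particle belongs to.
    position : (3,) ndarray
        Centre in nm, tomogram coordinates.
    orientation : (3, 3) ndarray
        Proper rotation mapping particle-local axes into tomogram axes
        (column-vector convention). Local +z is the outward (radial) axis,
        local +y the axial reference along the filament tangent.
    cc_score : float or None
        Cross-correlation against the alignment reference, in [-1, 1].
    truth_chain_id : int or None
        Ground-truth oligomer label; set only by the synthetic generator
        (-1 marks decoy particles).
    """

    particle_id: int
    tomogram_id: str
    filament_id: str
    position: np.ndarray
    orientation: np.ndarray
    cc_score: Optional[float] = None
    ring_index: Optional[int] = None
    azimuth_index: Optional[int] = None
    truth_chain_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if self.cc_score is not None and not -1.0 <= self.cc_score <= 1.0:
            raise ValueError(
                f"cc_score {self.cc_score} outside [-1, 1] for particle {self.particle_id}"
            )

    @property
    def outward_axis(self) -> np.ndarray:
        """World-frame direction of the particle's local +z (radial) axis."""
        return self.orientation[:, 2]

    @property
    def axial_reference(self) -> np.ndarray:
        """World-frame direction of the particle's local +y axis."""
        return self.orientation[:, 1]

    def copy(self, **changes) -> "Particle":
        p = replace(self, **changes)
        p.position = p.position.copy()
        p.orientation = p.orientation.copy()
        return p


@dataclass
class FilamentPath:
    """An ordered microtubule backbone trace plus its resampled nodes.

    ``control_points`` are the raw traced points; ``nodes`` are equidistant
    arc-length resampled points with unit ``tangents`` attached by
    :func:`tomolattice.geometry_core.build_local_frames` /
    :func:`tomolattice.picking.resample_path`.
    """

    tomogram_id: str
    filament_id: str
    control_points: np.ndarray
    nodes: Optional[np.ndarray] = None
    tangents: Optional[np.ndarray] = None
    spacing: Optional[float] = None

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float).reshape(-1, 3)
        if len(self.control_points) < 2:
            raise ValueError(
                f"filament {self.filament_id}: needs >= 2 control points, "
                f"got {len(self.control_points)}"
            )
        if self.nodes is not None:
            self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        if self.tangents is not None:
            self.tangents = np.asarray(self.tangents, dtype=float).reshape(-1, 3)

    @property
    def length(self) -> float:
        """Arc length in nm (over nodes when resampled, else control points)."""
        pts = self.nodes if self.nodes is not None else self.control_points
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    @property
    def key(self) -> tuple:
        return (self.tomogram_id, self.filament_id)


@dataclass
class PairRecord:
    """A candidate dimer pair and its geometry against the filament axis."""

    id_a: int
    id_b: int
    filament_id: str
    distance: float
    displacement: np.ndarray
    theta: Optional[float] = None
    pair_class: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id_a < self.id_b:
            raise ValueError("pair ids must satisfy id_a < id_b")
        self.displacement = np.asarray(self.displacement, dtype=float).reshape(3)
        if self.distance <= 0:
            raise ValueError("pair distance must be positive")


@dataclass
class Chain:
    """A connected group of particles representing one oligomer."""

    chain_id: int
    filament_id: str
    member_particle_ids: frozenset = field(default_factory=frozenset)

    @property
    def size(self) -> int:
        """Number of member dimers (WD40:WD40 picking units)."""
        return len(self.member_particle_ids)


@dataclass
class CoverageStats:
    """Per-filament decoration density."""

    filament_id: str
    particle_count: int
    filament_length: float
    particles_per_nm: float


@dataclass
class PickGridSpec:
    """Cylindrical oversampled picking grid parameters.

    Defaults follow the protocol used for LRRK2 on microtubules: 23 nm
    radius from the axis, 7 nm ring spacing along the path, 18 evenly
    spaced subunits per ring, 36 nm box (metadata only).
    """

    radius: float = 23.0
    ring_spacing: float = 7.0
    subunits_per_ring: int = 18
    box_size: float = 36.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.ring_spacing <= 0:
            raise ValueError("radius and ring_spacing must be positive")
        if self.subunits_per_ring < 1:
            raise ValueError("subunits_per_ring must be >= 1")


@dataclass
class LatticeSpec:
    """Ground-truth microtubule lattice: 1-start helix of tubulin subunits.

    For ``n_protofilaments`` strands the 1-start helical twist is
    360/n_pf degrees per subunit (left-handed, hence negative) with a
    0.94 nm rise; for 13 protofilaments this is the familiar
    twist = -27.7 deg, rise = 9.4 Angstrom parameterization. ``subunit_twist``
    may be overridden; ``None`` means derive it from the protofilament count.
    """

    n_protofilaments: int = 13
    tube_diameter: float = 30.0
    subunit_rise: float = 0.94
    subunit_twist: Optional[float] = None
    length: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_protofilaments < 1:
            raise ValueError("n_protofilaments must be >= 1")
        if min(self.tube_diameter, self.subunit_rise, self.length) <= 0:
            raise ValueError("diameter, rise and length must be positive")

    @property
    def twist(self) -> float:
        """Effective per-subunit azimuthal increment, degrees (signed)."""
        if self.subunit_twist is not None:
            return self.subunit_twist
        return -360.0 / self.n_protofilaments

    @property
    def radius(self) -> float:
        return self.tube_diameter / 2.0


_DEFAULT_CHAIN_PMF = {1: 0.38, 2: 0.25, 3: 0.17, 4: 0.10, 5: 0.06, 6: 0.04}


@dataclass
class DecorationSpec:
    """How oligomer chains are planted on a filament surface.

    ``mode='ring'`` places within-chain steps perpendicular to the axis
    (theta = 90 deg, ring-like oligomers); ``mode='helix'`` places
    right-handed azimuthal+axial steps at ``theta`` (default 33 deg, the
    active-like filament geometry). ``occupancy`` is the fraction of axial
    seed sites (spaced ``neighbor_spacing`` apart) that attempt to start a
    chain; chains closer than ``min_chain_separation`` to existing
    particles are rejected so distinct oligomers stay resolvable.
    ``ang_noise_sigma`` jitters each placement step's theta (and, through
    :func:`perturb_particles`, wobbles orientations); ``pos_noise_sigma``
    displaces final positions isotropically.
    """

    mode: str = "ring"
    theta: Optional[float] = None
    neighbor_spacing: float = 8.0
    binding_radius: float = 23.0
    chain_length_distribution: dict = field(
        default_factory=lambda: dict(_DEFAULT_CHAIN_PMF)
    )
    occupancy: float = 0.3
    pos_noise_sigma: float = 0.0
    ang_noise_sigma: float = 0.0
    min_chain_separation: float = 16.0
    cc_true: tuple = (0.6, 0.1)
    cc_false: tuple = (0.2, 0.08)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ring", "helix"):
            raise ValueError(f"unknown decoration mode {self.mode!r}")
        if self.theta is None:
            self.theta = 90.0 if self.mode == "ring" else 33.0
        if not 0.0 < self.theta < 180.0:
            raise ValueError("theta must lie in (0, 180)")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        total = sum(self.chain_length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("chain_length_distribution must sum to 1")
        if self.pos_noise_sigma < 0 or self.ang_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
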