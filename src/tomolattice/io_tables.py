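"""Particle-table and filament-trace readers/writers.

Three particle-table dialects are supported:

``star``
    A STAR loop (``data_particles``). Coordinates are 0-based voxel
    centres in pixels (``rlnCoordinateX/Y/Z``); optional origin shifts in
    Angstrom (``rlnOriginXAngst/...``) are subtracted as
    ``nm = coord_px * pixel_size_A / 10 - origin_A / 10``, following
    current subtomogram tooling. Orientations are ``rlnAngleRot/Tilt/Psi``
    in the zyz-relion convention. Extra columns ``ttParticleId`` and
    ``ttTruthChainId`` carry the dataset-unique id and (synthetic only)
    the ground-truth chain label; ``rlnAutopickFigureOfMerit`` carries the
    CC score.

``dynamo-tbl``
    Whitespace-separated 35-column table, no header. Columns honored
    (1-based): 1 tag, 4-6 shifts dx/dy/dz (px, added to the coordinate on
    read, written as 0), 7-9 Euler angles tdrot/tilt/narot (zxz-dynamo),
    10 CC score, 20 tomogram index, 21 filament index, 24-26 x/y/z (px).
    All other columns are written as 0 and ignored on read. Tomogram and
    filament ids are numeric in this dialect; they round-trip through the
    ``tomo_<n>`` / ``mt_<n>`` naming scheme.

``tsv``
    A plain tab-separated table in nm with zxz-dynamo Euler angles;
    lossless and human-readable, used for pairs/chains/truth reports too.

All positions are converted to nanometres on read; no module outside this
one sees pixels or Angstrom.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry_core import EULER_CONVENTIONS, euler_to_matrix, matrix_to_euler
from .models import FilamentPath, Particle

log = logging.getLogger(__name__)

__all__ = [
    "ParticleTableDialect",
    "STAR_DIALECT",
    "DYNAMO_DIALECT",
    "TSV_DIALECT",
    "read_particles",
    "write_particles",
    "read_filament_traces",
    "write_filament_traces",
    "write_dataset",
    "load_config",
]


@dataclass
class ParticleTableDialect:
    """Names a table format plus the unit/angle conventions it implies."""

    name: str  # star | dynamo-tbl | tsv
    pixel_size: float = 10.0  # Angstrom per pixel, for pixel-unit dialects
    euler_convention: str = "zyz-relion"

    def __post_init__(self) -> None:
        if self.name not in ("star", "dynamo-tbl", "tsv"):
            raise ValueError(f"unknown dialect {self.name!r}")
        if self.name in ("star", "dynamo-tbl") and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive for pixel dialects")
        if self.euler_convention not in EULER_CONVENTIONS:
            raise ValueError(f"unsupported Euler convention {self.euler_convention!r}")


STAR_DIALECT = ParticleTableDialect("star", pixel_size=10.0, euler_convention="zyz-relion")
DYNAMO_DIALECT = ParticleTableDialect("dynamo-tbl", pixel_size=10.0, euler_convention="zxz-dynamo")
TSV_DIALECT = ParticleTableDialect("tsv", euler_convention="zxz-dynamo")


# ---------------------------------------------------------------- STAR layer

def _parse_star_loop(path: Path) -> pd.DataFrame:
    """Minimal STAR loop parser: first data_ block with a loop_."""
    columns: List[str] = []
    rows: List[List[str]] = []
    in_loop = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                if rows:
                    break
                continue
            if line.startswith("data_"):
                if rows:
                    break
                continue
            if line == "loop_":
                in_loop = True
                columns, rows = [], []
                continue
            if line.startswith("_"):
                if in_loop:
                    columns.append(line.split()[0].lstrip("_"))
                continue
            if in_loop and columns:
                vals = line.split()
                if len(vals) != len(columns):
                    raise ValueError(
                        f"{path}: row has {len(vals)} fields, expected {len(columns)}"
                    )
                rows.append(vals)
    if not columns:
        raise ValueError(f"{path}: no STAR loop found")
    return pd.DataFrame(rows, columns=columns)


def _write_star_loop(df: pd.DataFrame, path: Path, block: str = "particles") -> None:
    with open(path, "w") as fh:
        fh.write(f"\ndata_{block}\n\nloop_\n")
        for i, col in enumerate(df.columns, start=1):
            fh.write(f"_{col} #{i}\n")
        for _, row in df.iterrows():
            fh.write(" ".join(str(v) for v in row.to_list()) + "\n")


_TRUTH_SENTINEL = -999  # "no ground truth" marker (decoys use -1)

_STAR_REQUIRED = [
    "rlnCoordinateX",
    "rlnCoordinateY",
    "rlnCoordinateZ",
    "rlnAngleRot",
    "rlnAngleTilt",
    "rlnAnglePsi",
]


def _read_star(path: Path, dialect: ParticleTableDialect) -> List[Particle]:
    df = _parse_star_loop(path)
    for col in _STAR_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required STAR column {col}")
    apix = dialect.pixel_size
    n = len(df)
    coords = df[["rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ"]].astype(float).to_numpy()
    pos_nm = coords * apix / 10.0
    for axis, col in enumerate(["rlnOriginXAngst", "rlnOriginYAngst", "rlnOriginZAngst"]):
        if col in df.columns:
            pos_nm[:, axis] -= df[col].astype(float).to_numpy() / 10.0
    angles = df[["rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"]].astype(float).to_numpy()
    particles = []
    for i in range(n):
        cc = None
        if "rlnAutopickFigureOfMerit" in df:
            cc = float(df["rlnAutopickFigureOfMerit"].iloc[i])
            if not -1.0 <= cc <= 1.0:
                cc = None
        truth = None
        if "ttTruthChainId" in df:
            truth = int(df["ttTruthChainId"].iloc[i])
            if truth == _TRUTH_SENTINEL:
                truth = None
        particles.append(
            Particle(
                particle_id=int(df["ttParticleId"].iloc[i]) if "ttParticleId" in df else i,
                tomogram_id=str(df["rlnTomoName"].iloc[i]) if "rlnTomoName" in df else "tomo_1",
                filament_id=(
                    f"mt_{int(df['rlnHelicalTubeID'].iloc[i])}"
                    if "rlnHelicalTubeID" in df
                    else "mt_1"
                ),
                position=pos_nm[i],
                orientation=euler_to_matrix(angles[i], dialect.euler_convention),
                cc_score=cc,
                truth_chain_id=truth,
            )
        )
    return particles


def _fil_index(filament_id: str) -> int:
    m = re.search(r"(\d+)$", str(filament_id))
    return int(m.group(1)) if m else 0


def _write_star(particles: Sequence[Particle], path: Path, dialect: ParticleTableDialect) -> None:
    apix = dialect.pixel_size
    rows = []
    for p in particles:
        z1, x, z2 = matrix_to_euler(p.orientation, dialect.euler_convention)
        px = p.position * 10.0 / apix
        rows.append(
            {
                "ttParticleId": p.particle_id,
                "rlnTomoName": p.tomogram_id,
                "rlnHelicalTubeID": _fil_index(p.filament_id),
                "rlnCoordinateX": f"{px[0]:.8f}",
                "rlnCoordinateY": f"{px[1]:.8f}",
                "rlnCoordinateZ": f"{px[2]:.8f}",
                "rlnAngleRot": f"{z1:.8f}",
                "rlnAngleTilt": f"{x:.8f}",
                "rlnAnglePsi": f"{z2:.8f}",
                # STAR rows are whitespace-delimited, so absent values use
                # out-of-range sentinels rather than empty cells
                "rlnAutopickFigureOfMerit": "2.0" if p.cc_score is None else f"{p.cc_score:.6f}",
                "ttTruthChainId": _TRUTH_SENTINEL if p.truth_chain_id is None else p.truth_chain_id,
            }
        )
    star_cols = [
        "ttParticleId", "rlnTomoName", "rlnHelicalTubeID",
        "rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ",
        "rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi",
        "rlnAutopickFigureOfMerit", "ttTruthChainId",
    ]
    df = pd.DataFrame(rows, columns=star_cols)
    if rows and all(r["rlnAutopickFigureOfMerit"] == "2.0" for r in rows):
        df = df.drop(columns=["rlnAutopickFigureOfMerit"])
    if rows and all(r["ttTruthChainId"] == _TRUTH_SENTINEL for r in rows):
        df = df.drop(columns=["ttTruthChainId"])
    _write_star_loop(df, path)


# -------------------------------------------------------------- Dynamo layer

_TBL_NCOL = 35


def _read_tbl(path: Path, dialect: ParticleTableDialect) -> List[Particle]:
    if path.stat().st_size == 0:
        return []
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return []
    if data.shape[1] != _TBL_NCOL:
        raise ValueError(
            f"{path}: expected {_TBL_NCOL}-column Dynamo table, got {data.shape[1]}"
        )
    apix = dialect.pixel_size
    particles = []
    for row in data:
        pos_px = row[23:26] + row[3:6]  # coordinate + shift
        particles.append(
            Particle(
                particle_id=int(row[0]),
                tomogram_id=f"tomo_{int(row[19])}",
                filament_id=f"mt_{int(row[20])}",
                position=pos_px * apix / 10.0,
                orientation=euler_to_matrix(row[6:9], "zxz-dynamo"),
                cc_score=float(row[9]) if -1.0 <= row[9] <= 1.0 else None,
            )
        )
    return particles


def _write_tbl(particles: Sequence[Particle], path: Path, dialect: ParticleTableDialect) -> None:
    apix = dialect.pixel_size
    out = np.zeros((len(particles), _TBL_NCOL))
    for i, p in enumerate(particles):
        z1, x, z2 = matrix_to_euler(p.orientation, "zxz-dynamo")
        out[i, 0] = p.particle_id
        out[i, 1] = 1  # aligned
        out[i, 2] = 1  # averaged
        out[i, 6:9] = (z1, x, z2)
        out[i, 9] = p.cc_score if p.cc_score is not None else 2.0  # out-of-range sentinel
        out[i, 19] = _fil_index(p.tomogram_id)
        out[i, 20] = _fil_index(p.filament_id)
        out[i, 23:26] = p.position * 10.0 / apix
    np.savetxt(path, out, fmt="%.12g")


# ----------------------------------------------------------------- TSV layer

_TSV_COLS = [
    "particle_id",
    "tomogram_id",
    "filament_id",
    "x_nm",
    "y_nm",
    "z_nm",
    "euler_z1",
    "euler_x",
    "euler_z2",
    "cc_score",
    "truth_chain_id",
]


def _read_tsv(path: Path, dialect: ParticleTableDialect) -> List[Particle]:
    df = pd.read_csv(path, sep="\t")
    for col in _TSV_COLS[:9]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")
    particles = []
    for _, row in df.iterrows():
        cc = row.get("cc_score", np.nan)
        tc = row.get("truth_chain_id", np.nan)
        particles.append(
            Particle(
                particle_id=int(row["particle_id"]),
                tomogram_id=str(row["tomogram_id"]),
                filament_id=str(row["filament_id"]),
                position=np.array([row["x_nm"], row["y_nm"], row["z_nm"]]),
                orientation=euler_to_matrix(
                    (row["euler_z1"], row["euler_x"], row["euler_z2"]),
                    dialect.euler_convention,
                ),
                cc_score=None if pd.isna(cc) else float(cc),
                truth_chain_id=None if pd.isna(tc) else int(tc),
            )
        )
    return particles


def _write_tsv(particles: Sequence[Particle], path: Path, dialect: ParticleTableDialect) -> None:
    rows = []
    for p in particles:
        z1, x, z2 = matrix_to_euler(p.orientation, dialect.euler_convention)
        rows.append(
            {
                "particle_id": p.particle_id,
                "tomogram_id": p.tomogram_id,
                "filament_id": p.filament_id,
                "x_nm": f"{p.position[0]:.9f}",
                "y_nm": f"{p.position[1]:.9f}",
                "z_nm": f"{p.position[2]:.9f}",
                "euler_z1": f"{z1:.9f}",
                "euler_x": f"{x:.9f}",
                "euler_z2": f"{z2:.9f}",
                "cc_score": "" if p.cc_score is None else f"{p.cc_score:.6f}",
                "truth_chain_id": "" if p.truth_chain_id is None else p.truth_chain_id,
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLS).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- facade

_READERS = {"star": _read_star, "dynamo-tbl": _read_tbl, "tsv": _read_tsv}
_WRITERS = {"star": _write_star, "dynamo-tbl": _write_tbl, "tsv": _write_tsv}


def read_particles(path, dialect: ParticleTableDialect = STAR_DIALECT) -> List[Particle]:
    """Read a particle table; positions in nm, orientations as matrices."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"particle table not found: {path}")
    particles = _READERS[dialect.name](path, dialect)
    log.info("read %d particles from %s (%s)", len(particles), path, dialect.name)
    return particles


def write_particles(
    particles: Sequence[Particle], path, dialect: ParticleTableDialect = STAR_DIALECT
) -> None:
    """Write a particle table re-readable under the same dialect."""
    path = Path(path)
    try:
        _WRITERS[dialect.name](particles, path, dialect)
    except OSError as exc:
        raise OSError(f"cannot write particle table {path}: {exc}") from exc
    log.info("wrote %d particles to %s (%s)", len(particles), path, dialect.name)


# ------------------------------------------------------------------- traces

def read_filament_traces(path, pixel_size: Optional[float] = None) -> List[FilamentPath]:
    """Read an IMOD-style point-list export: object contour x y z per row.

    One FilamentPath per (object, contour); object maps to the tomogram
    id, contour to the filament id. Coordinates are nm unless
    ``pixel_size`` (Angstrom/px) is given, in which case they are pixels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    groups: Dict[tuple, List[List[float]]] = {}
    order: List[tuple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                obj, cont = int(float(parts[0])), int(float(parts[1]))
                xyz = [float(v) for v in parts[2:5]]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric row") from None
            key = (obj, cont)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(xyz)
    scale = (pixel_size / 10.0) if pixel_size else 1.0
    paths = []
    for obj, cont in order:
        pts = np.array(groups[(obj, cont)]) * scale
        if len(pts) < 2:
            raise ValueError(
                f"{path}: contour {cont} of object {obj} has a single point"
            )
        paths.append(
            FilamentPath(
                tomogram_id=f"tomo_{obj}", filament_id=f"mt_{cont}", control_points=pts
            )
        )
    log.info("read %d filament traces from %s", len(paths), path)
    return paths


def write_filament_traces(paths: Sequence[FilamentPath], out_path) -> None:
    """Write traces as object contour x y z rows (nm)."""
    with open(out_path, "w") as fh:
        fh.write("# object contour x_nm y_nm z_nm\n")
        for p in paths:
            obj = _fil_index(p.tomogram_id) or 1
            cont = _fil_index(p.filament_id) or 1
            for pt in p.control_points:
                fh.write(f"{obj} {cont} {pt[0]:.9f} {pt[1]:.9f} {pt[2]:.9f}\n")


# -------------------------------------------------------------- dataset i/o

def write_dataset(ds, out_dir, dialect: ParticleTableDialect = STAR_DIALECT, config: Optional[dict] = None) -> dict:
    """Serialize a SyntheticDataset: particles + traces + truth (+ config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = {"star": "star", "dynamo-tbl": "tbl", "tsv": "tsv"}[dialect.name]
    files = {
        "particles": out / f"particles.{suffix}",
        "traces": out / "traces.txt",
        "truth": out / "truth.tsv",
    }
    write_particles(ds.particles, files["particles"], dialect)
    write_filament_traces(ds.paths, files["traces"])
    ds.truth.to_csv(files["truth"], sep="\t", index=False)
    if config is not None:
        files["config"] = out / "config.yaml"
        with open(files["config"], "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=False)
    return files


def load_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return cfg
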