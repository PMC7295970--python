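"""Readers and writers: LAMMPS text dump, extended XYZ, CSV series, config.

The dump dialect is the standard text dump (ITEM: TIMESTEP / NUMBER OF
ATOMS / BOX BOUNDS pp pp pp / ATOMS with named columns).  Recognised
columns: ``id type mass x y z ix iy iz c_stress[1..6] c_voro[1]``; the
``type`` column carries the species label.  Triclinic BOX BOUNDS (tilt
factors) are rejected.  Frame times are the TIMESTEP value multiplied by
``time_per_step`` (default 1 ps per step).

All CSV series carry ``# name:`` and ``# unit:`` header lines and
round-trip through :func:`read_series`/:func:`write_series`.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import yaml

from .frames import Box, ParticleFrame, ScalarTimeSeries, Trajectory

__all__ = [
    "ParseError",
    "read_lammps_dump",
    "write_lammps_dump",
    "read_xyz",
    "write_xyz",
    "read_trajectory",
    "write_trajectory",
    "read_series",
    "write_series",
    "RunConfig",
]

_STRESS_COLS = [f"c_stress[{i}]" for i in range(1, 7)]
_VORO_COL = "c_voro[1]"


class ParseError(ValueError):
    """Malformed trajectory file; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# --------------------------------------------------------------------------
# LAMMPS text dump
# --------------------------------------------------------------------------

def write_lammps_dump(traj: Trajectory, path, time_per_step: float = 1.0) -> None:
    """Write a trajectory as a LAMMPS-style text dump.

    Optional per-atom stress, volume and image-flag columns are emitted
    when present on the first frame.  Frame times are divided by
    ``time_per_step`` to produce the TIMESTEP value.
    """
    first = traj[0]
    cols = ["id", "type", "mass", "x", "y", "z"]
    if first.images is not None:
        cols += ["ix", "iy", "iz"]
    if first.per_atom_stress is not None:
        cols += _STRESS_COLS
    if first.per_atom_volume is not None:
        cols += [_VORO_COL]
    with open(path, "w") as fh:
        for frame in traj:
            step = frame.time / time_per_step
            step_repr = str(int(round(step))) if abs(step - round(step)) < 1e-9 else repr(step)
            fh.write("ITEM: TIMESTEP\n" + step_repr + "\n")
            fh.write(f"ITEM: NUMBER OF ATOMS\n{frame.n_atoms}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for lo, hi in frame.box.bounds:
                fh.write(f"{lo:.10g} {hi:.10g}\n")
            fh.write("ITEM: ATOMS " + " ".join(cols) + "\n")
            species = frame.species if frame.species is not None else np.full(frame.n_atoms, "1")
            for i in range(frame.n_atoms):
                parts = [
                    str(int(frame.ids[i])),
                    str(species[i]),
                    f"{frame.masses[i]:.10g}",
                    f"{frame.coordinates[i, 0]:.10g}",
                    f"{frame.coordinates[i, 1]:.10g}",
                    f"{frame.coordinates[i, 2]:.10g}",
                ]
                if frame.images is not None:
                    parts += [str(int(v)) for v in frame.images[i]]
                if frame.per_atom_stress is not None:
                    parts += [f"{v:.10g}" for v in frame.per_atom_stress[i]]
                if frame.per_atom_volume is not None:
                    parts += [f"{frame.per_atom_volume[i]:.10g}"]
                fh.write(" ".join(parts) + "\n")


def read_lammps_dump(path, time_per_step: float = 1.0, constant_identity: Optional[bool] = None) -> Trajectory:
    """Parse a LAMMPS text dump into a :class:`Trajectory`.

    Raises :class:`ParseError` with a line number on malformed headers,
    inconsistent atom counts, triclinic boxes or unknown columns.
    ``constant_identity`` defaults to automatic: identity is enforced only
    if all frames share the same id set.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: List[ParticleFrame] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise ParseError(path, i + 1, f"expected 'ITEM: TIMESTEP', got {lines[i]!r}")
        try:
            step = float(lines[i + 1])
        except (IndexError, ValueError):
            raise ParseError(path, i + 2, "missing or non-numeric timestep value")
        if i + 2 >= n_lines or not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise ParseError(path, i + 3, "expected 'ITEM: NUMBER OF ATOMS'")
        try:
            n_atoms = int(lines[i + 3])
        except (IndexError, ValueError):
            raise ParseError(path, i + 4, "missing or non-integer atom count")
        if i + 4 >= n_lines or not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
            raise ParseError(path, i + 5, "expected 'ITEM: BOX BOUNDS'")
        bounds_spec = lines[i + 4].split()[3:]
        if any(tag in ("xy", "xz", "yz") for tag in bounds_spec):
            raise ParseError(path, i + 5, "triclinic boxes are not supported")
        bounds = np.empty((3, 2))
        for d in range(3):
            parts = lines[i + 5 + d].split()
            if len(parts) < 2:
                raise ParseError(path, i + 6 + d, "box bounds line needs 'lo hi'")
            if len(parts) > 2:
                raise ParseError(path, i + 6 + d, "triclinic boxes are not supported")
            bounds[d] = [float(parts[0]), float(parts[1])]
        if not lines[i + 8].startswith("ITEM: ATOMS"):
            raise ParseError(path, i + 9, "expected 'ITEM: ATOMS'")
        cols = lines[i + 8].split()[2:]
        known = {"id", "type", "mass", "x", "y", "z", "ix", "iy", "iz", _VORO_COL, *_STRESS_COLS}
        unknown = [c for c in cols if c not in known]
        if unknown:
            raise ParseError(path, i + 9, f"unknown columns: {unknown}")
        for req in ("x", "y", "z"):
            if req not in cols:
                raise ParseError(path, i + 9, f"missing required column {req!r}")
        col_idx = {c: j for j, c in enumerate(cols)}

        start = i + 9
        if start + n_atoms > n_lines:
            raise ParseError(path, n_lines, f"frame at line {i + 1} declares {n_atoms} atoms but file ends early")
        ids = np.zeros(n_atoms, dtype=int)
        species = np.empty(n_atoms, dtype=object)
        masses = np.ones(n_atoms)
        coords = np.empty((n_atoms, 3))
        images = np.zeros((n_atoms, 3), dtype=int) if "ix" in col_idx else None
        stress = np.empty((n_atoms, 6)) if all(c in col_idx for c in _STRESS_COLS) else None
        volumes = np.empty(n_atoms) if _VORO_COL in col_idx else None
        for a in range(n_atoms):
            parts = lines[start + a].split()
            if parts and parts[0].startswith("ITEM:"):
                raise ParseError(path, start + a + 1, "atom count inconsistent with declared NUMBER OF ATOMS")
            if len(parts) != len(cols):
                raise ParseError(path, start + a + 1, f"expected {len(cols)} fields, got {len(parts)}")
            try:
                ids[a] = int(parts[col_idx["id"]]) if "id" in col_idx else a + 1
                coords[a] = [float(parts[col_idx[c]]) for c in ("x", "y", "z")]
                species[a] = parts[col_idx["type"]] if "type" in col_idx else "1"
                if "mass" in col_idx:
                    masses[a] = float(parts[col_idx["mass"]])
                if images is not None:
                    images[a] = [int(parts[col_idx[c]]) for c in ("ix", "iy", "iz")]
                if stress is not None:
                    stress[a] = [float(parts[col_idx[c]]) for c in _STRESS_COLS]
                if volumes is not None:
                    volumes[a] = float(parts[col_idx[_VORO_COL]])
            except ValueError as exc:
                raise ParseError(path, start + a + 1, f"bad field: {exc}")
        frames.append(
            ParticleFrame(
                time=step * time_per_step,
                box=Box(bounds),
                coordinates=coords,
                masses=masses,
                species=species.astype(str),
                per_atom_stress=stress,
                per_atom_volume=volumes,
                ids=ids,
                images=images,
            )
        )
        i = start + n_atoms
    if not frames:
        raise ParseError(path, 1, "no frames found")
    if constant_identity is None:
        ref = frames[0].ids
        constant_identity = all(
            f.n_atoms == frames[0].n_atoms and np.array_equal(f.ids, ref) for f in frames
        )
    return Trajectory(frames, constant_identity=constant_identity)


# --------------------------------------------------------------------------
# extended XYZ
# --------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path) -> None:
    """Write a trajectory as extended XYZ (species, positions, masses)."""
    with open(path, "w") as fh:
        for frame in traj:
            l = frame.box.lengths
            o = frame.box.origin
            fh.write(f"{frame.n_atoms}\n")
            fh.write(
                f'Lattice="{l[0]:.10g} 0 0 0 {l[1]:.10g} 0 0 0 {l[2]:.10g}" '
                f'Origin="{o[0]:.10g} {o[1]:.10g} {o[2]:.10g}" '
                f"Properties=species:S:1:pos:R:3:mass:R:1:id:I:1 "
                f"Time={frame.time:.10g}\n"
            )
            species = frame.species if frame.species is not None else np.full(frame.n_atoms, "W")
            for a in range(frame.n_atoms):
                fh.write(
                    f"{species[a]} {frame.coordinates[a, 0]:.10g} {frame.coordinates[a, 1]:.10g} "
                    f"{frame.coordinates[a, 2]:.10g} {frame.masses[a]:.10g} {int(frame.ids[a])}\n"
                )


def _parse_xyz_comment(path, lineno: int, comment: str) -> dict:
    fields = {}
    key = ""
    i = 0
    token = ""
    in_quote = False
    parts: List[str] = []
    for ch in comment:
        if ch == '"':
            in_quote = not in_quote
            continue
        if ch.isspace() and not in_quote:
            if token:
                parts.append(token)
                token = ""
        else:
            token += ch
    if token:
        parts.append(token)
    for part in parts:
        if "=" in part:
            k, v = part.split("=", 1)
            fields[k] = v
    return fields


def read_xyz(path) -> Trajectory:
    """Parse an extended-XYZ file written by :func:`write_xyz`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: List[ParticleFrame] = []
    i = 0
    t_fallback = 0.0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i])
        except ValueError:
            raise ParseError(path, i + 1, f"expected atom count, got {lines[i]!r}")
        if i + 1 >= len(lines):
            raise ParseError(path, i + 2, "missing comment line")
        fields = _parse_xyz_comment(path, i + 2, lines[i + 1])
        if "Lattice" not in fields:
            raise ParseError(path, i + 2, "extended XYZ requires a Lattice entry")
        lat = np.array([float(v) for v in fields["Lattice"].split()])
        if lat.size != 9:
            raise ParseError(path, i + 2, "Lattice must have 9 numbers")
        lat = lat.reshape(3, 3)
        if np.any(np.abs(lat - np.diag(np.diag(lat))) > 1e-10):
            raise ParseError(path, i + 2, "non-orthorhombic Lattice is not supported")
        origin = np.array([float(v) for v in fields.get("Origin", "0 0 0").split()])
        time = float(fields.get("Time", t_fallback))
        if i + 2 + n_atoms > len(lines):
            raise ParseError(path, len(lines), f"frame at line {i + 1} truncated")
        species = np.empty(n_atoms, dtype=object)
        coords = np.empty((n_atoms, 3))
        masses = np.ones(n_atoms)
        ids = np.arange(1, n_atoms + 1)
        for a in range(n_atoms):
            parts = lines[i + 2 + a].split()
            if len(parts) < 4:
                raise ParseError(path, i + 3 + a, "atom line needs species + 3 coordinates")
            species[a] = parts[0]
            coords[a] = [float(v) for v in parts[1:4]]
            if len(parts) >= 5:
                masses[a] = float(parts[4])
            if len(parts) >= 6:
                ids[a] = int(parts[5])
        frames.append(
            ParticleFrame(
                time=time,
                box=Box.from_lengths(np.diag(lat), origin),
                coordinates=coords,
                masses=masses,
                species=species.astype(str),
                ids=ids,
            )
        )
        t_fallback = time + 1.0
        i += 2 + n_atoms
    if not frames:
        raise ParseError(path, 1, "no frames found")
    ref = frames[0].ids
    const = all(f.n_atoms == frames[0].n_atoms and np.array_equal(f.ids, ref) for f in frames)
    return Trajectory(frames, constant_identity=const)


def read_trajectory(path, format: Optional[str] = None, **kwargs) -> Trajectory:
    """Read a trajectory, sniffing the format from the suffix/content if needed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.suffix in (".xyz", ".extxyz"):
            format = "xyz"
        elif path.suffix in (".dump", ".lammpstrj"):
            format = "lammps"
        else:
            with open(path) as fh:
                first = fh.readline()
            format = "lammps" if first.startswith("ITEM:") else "xyz"
    if format == "lammps":
        return read_lammps_dump(path, **kwargs)
    if format == "xyz":
        return read_xyz(path, **kwargs)
    raise ValueError(f"unknown trajectory format {format!r}")


def write_trajectory(traj: Trajectory, path, format: Optional[str] = None, **kwargs) -> None:
    path = Path(path)
    if format is None:
        format = "xyz" if path.suffix in (".xyz", ".extxyz") else "lammps"
    if format == "lammps":
        write_lammps_dump(traj, path, **kwargs)
    elif format == "xyz":
        write_xyz(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


# --------------------------------------------------------------------------
# CSV scalar series
# --------------------------------------------------------------------------

def write_series(series: ScalarTimeSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name: {series.name}\n")
        fh.write(f"# unit: {series.unit}\n")
        fh.write("time_ps,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.10g},{v:.10g}\n")


def read_series(path) -> ScalarTimeSeries:
    name = ""
    unit = ""
    times = []
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("name:"):
                    name = body[5:].strip()
                elif body.startswith("unit:"):
                    unit = body[5:].strip()
                continue
            if line.startswith("time"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(path, lineno, f"expected 'time,value', got {line!r}")
            times.append(float(parts[0]))
            values.append(float(parts[1]))
    return ScalarTimeSeries(np.array(times), np.array(values), unit=unit, name=name)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis parameters with usable defaults for the demo pipeline.

    Every field has a default; precedence when assembling a run is
    CLI flags > config file > these defaults.
    """

    input_path: Optional[str] = None
    format: Optional[str] = None  # lammps | xyz | None = sniff
    output_dir: str = "nanocav_out"
    medium: str = "water"
    grid_spacing: float = 2.0  # Å
    probe_radius: float = 3.0  # Å
    min_cavity_volume: float = 500.0  # Å³
    smoothing_window: float = 1.0  # ps
    msd_fit_window: Tuple[float, float] = (0.2, 0.8)
    gk_cutoff: Optional[float] = None  # ps
    collapse_fraction: float = 0.01
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "msd_fit_window" in data:
            data["msd_fit_window"] = tuple(data["msd_fit_window"])
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        data = dataclasses.asdict(self)
        data["msd_fit_window"] = list(self.msd_fit_window)
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        """Short content hash of the configuration, for run logs."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **{k: v for k, v in kwargs.items() if v is not None})
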