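"""In-memory containers for particle trajectories and scalar series.

Trajectory data live in the MD dump unit system: coordinates in Å, time in
ps, masses in amu, per-atom virial stress in atm·Å³ (stress × volume, the
dump convention) and per-atom volumes in Å³.  Boxes are orthorhombic and
periodic in all three directions; triclinic cells are rejected at the I/O
layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

__all__ = ["Box", "ParticleFrame", "Trajectory", "ScalarTimeSeries", "TransportEstimate"]


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic simulation cell, bounds in Å."""

    bounds: np.ndarray  # (3, 2) [lo, hi] per axis

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.shape != (3, 2):
            raise ValueError(f"bounds must have shape (3, 2), got {b.shape}")
        if np.any(b[:, 1] <= b[:, 0]):
            raise ValueError("box upper bounds must exceed lower bounds")
        object.__setattr__(self, "bounds", b)

    @classmethod
    def from_lengths(cls, lengths: Sequence[float], origin: Sequence[float] = (0.0, 0.0, 0.0)) -> "Box":
        o = np.asarray(origin, dtype=float)
        l = np.asarray(lengths, dtype=float)
        return cls(np.column_stack([o, o + l]))

    @property
    def lengths(self) -> np.ndarray:
        return self.bounds[:, 1] - self.bounds[:, 0]

    @property
    def origin(self) -> np.ndarray:
        return self.bounds[:, 0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        """Reduce coordinates into [lo, hi) under periodic wrapping."""
        return self.origin + np.mod(coords - self.origin, self.lengths)

    def center(self) -> np.ndarray:
        return self.origin + 0.5 * self.lengths


@dataclass
class ParticleFrame:
    """One time-stamped frame of particle data.

    coordinates may lie outside the box (e.g. unwrapped diffusive paths);
    they are always reducible into the box by periodic wrapping.  Optional
    per-atom fields must match the particle count exactly.
    """

    time: float  # ps
    box: Box
    coordinates: np.ndarray  # (N, 3) Å
    masses: np.ndarray  # (N,) amu
    species: Optional[np.ndarray] = None  # (N,) labels
    per_atom_stress: Optional[np.ndarray] = None  # (N, 6) atm·Å³ (xx yy zz xy xz yz)
    per_atom_volume: Optional[np.ndarray] = None  # (N,) Å³
    ids: Optional[np.ndarray] = None  # (N,) int
    images: Optional[np.ndarray] = None  # (N, 3) int periodic image flags

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        n = self.coordinates.shape[0]
        if n < 1 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be a non-empty (N, 3) array")
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n,):
            raise ValueError(f"masses must have shape ({n},)")
        if self.species is not None:
            self.species = np.asarray(self.species)
            if self.species.shape != (n,):
                raise ValueError(f"species must have shape ({n},)")
        if self.per_atom_stress is not None:
            self.per_atom_stress = np.asarray(self.per_atom_stress, dtype=float)
            if self.per_atom_stress.shape != (n, 6):
                raise ValueError(f"per_atom_stress must have shape ({n}, 6)")
        if self.per_atom_volume is not None:
            self.per_atom_volume = np.asarray(self.per_atom_volume, dtype=float)
            if self.per_atom_volume.shape != (n,):
                raise ValueError(f"per_atom_volume must have shape ({n},)")
        if self.ids is None:
            self.ids = np.arange(1, n + 1, dtype=int)
        else:
            self.ids = np.asarray(self.ids, dtype=int)
            if self.ids.shape != (n,):
                raise ValueError(f"ids must have shape ({n},)")
        if self.images is not None:
            self.images = np.asarray(self.images, dtype=int)
            if self.images.shape != (n, 3):
                raise ValueError(f"images must have shape ({n}, 3)")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    @property
    def total_mass(self) -> float:
        """Total particle mass in amu."""
        return float(self.masses.sum())

    def wrapped_coordinates(self) -> np.ndarray:
        return self.box.wrap(self.coordinates)

    def unwrapped_coordinates(self) -> np.ndarray:
        """Coordinates with periodic image flags applied, if present."""
        if self.images is None:
            return self.coordinates
        return self.coordinates + self.images * self.box.lengths


class Trajectory:
    """Ordered frames with strictly increasing times.

    By default particle identity (the id set) must be constant across
    frames.  Trajectories whose cavity grows shed interior particles frame
    by frame; construct those with ``constant_identity=False`` and use
    :meth:`common_ids` to recover the always-retained subset.
    """

    def __init__(self, frames: Sequence[ParticleFrame], constant_identity: bool = True):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        times = np.array([f.time for f in frames])
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if constant_identity:
            ref = frames[0].ids
            for i, f in enumerate(frames[1:], start=1):
                if f.n_atoms != frames[0].n_atoms or not np.array_equal(f.ids, ref):
                    raise ValueError(
                        f"frame {i} breaks constant particle identity; "
                        "pass constant_identity=False for variable-count trajectories"
                    )
        self.frames: List[ParticleFrame] = frames
        self.constant_identity = constant_identity

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def common_ids(self) -> np.ndarray:
        """Sorted ids present in every frame."""
        common = set(self.frames[0].ids.tolist())
        for f in self.frames[1:]:
            common &= set(f.ids.tolist())
        return np.array(sorted(common), dtype=int)


@dataclass
class ScalarTimeSeries:
    """A labelled scalar trace: times (ps), values, unit string."""

    times: np.ndarray
    values: np.ndarray
    unit: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class TransportEstimate:
    """A transport coefficient with its uncertainty and method metadata."""

    value: float
    standard_error: float
    unit: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.standard_error < 0:
            raise ValueError("standard_error must be >= 0")
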