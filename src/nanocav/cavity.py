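"""Cavity (void) detection and geometry in periodic particle frames.

The detector replaces the interactive surface-mesh construction used in MD
visualization tools with a deterministic probe-sphere occupancy method:

1. sample the box on a regular grid and mark as *core* every voxel whose
   centre lies farther than ``probe_radius`` from all particles (periodic
   minimum-image distances via a KD-tree);
2. dilate the core by the probe radius (a point belongs to the cavity if
   some probe sphere covering it contains no particle — the "rolling probe"
   definition, which restores the particle-boundary surface that the raw
   core systematically underestimates by one probe radius);
3. label connected components with periodic-aware connectivity and keep the
   largest one above a minimum-volume threshold as *the* cavity; smaller
   voids are counted separately (instantaneously nucleated tiny bubbles).

Geometry is measured on a triangulated isosurface of the signed distance
field (marching cubes): surface area from the mesh triangles, enclosed
volume by divergence-theorem accumulation, and the sphericity index

    Ψ = π^(1/3) · (6 V_c)^(2/3) / A_c,

which is 1 for a perfect sphere and decreases as the cavity deviates from
sphericity (the sphere minimises area at fixed volume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .frames import ParticleFrame

__all__ = ["CavityField", "CavityMetrics", "MeshError", "detect_cavity", "cavity_metrics", "mesh_metrics"]

#: Default voxel edge (Å) for the occupancy grid.
DEFAULT_GRID_SPACING = 2.0
#: Default probe-sphere radius (Å), about the radius of a water molecule.
DEFAULT_PROBE_RADIUS = 3.0
#: Voids smaller than this (Å³, ~17 water molecules) are thermal noise, not cavities.
DEFAULT_MIN_VOLUME = 500.0


class MeshError(RuntimeError):
    """Raised when a cavity surface cannot be triangulated into a closed mesh."""


@dataclass
class CavityMetrics:
    """Cavity geometry at one time point.

    volume_c (Å³) and area_c (Å²) come from the triangulated surface;
    effective_radius = (3·V_c/4π)^(1/3) and sphericity = π^(1/3)(6V_c)^(2/3)/A_c.
    """

    volume_c: float
    area_c: float

    def __post_init__(self) -> None:
        if self.volume_c < 0 or self.area_c < 0:
            raise ValueError("volume and area must be non-negative")

    @property
    def effective_radius(self) -> float:
        return (3.0 * self.volume_c / (4.0 * math.pi)) ** (1.0 / 3.0)

    @property
    def sphericity(self) -> float:
        if self.area_c == 0:
            return float("nan")
        return math.pi ** (1.0 / 3.0) * (6.0 * self.volume_c) ** (2.0 / 3.0) / self.area_c


@dataclass
class CavityField:
    """Occupancy-grid view of the empty space in one frame.

    ``signed_distance`` holds (distance to core region − probe_radius) per
    voxel: negative inside the cavity, zero on its surface.  ``labels``
    assigns each cavity voxel a component id (periodic-aware); label
    ``largest_label`` is the reported cavity (0 when no void exceeded the
    minimum volume).  ``secondary_volumes`` lists the voxel volumes of the
    other above-threshold voids.
    """

    origin: np.ndarray  # (3,) Å
    spacing: np.ndarray  # (3,) Å actual per-axis voxel edge
    core_mask: np.ndarray  # voxels farther than probe from every particle
    cavity_mask: np.ndarray  # core dilated by the probe radius
    signed_distance: np.ndarray
    labels: np.ndarray
    largest_label: int
    probe_radius: float
    min_volume: float
    secondary_volumes: List[float]

    @property
    def has_cavity(self) -> bool:
        return self.largest_label > 0

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_voxels(self) -> float:
        """Voxel-counting estimate of the largest cavity's volume (Å³)."""
        if not self.has_cavity:
            return 0.0
        return float(np.count_nonzero(self.labels == self.largest_label)) * self.voxel_volume

    @property
    def secondary_void_count(self) -> int:
        return len(self.secondary_volumes)


def _periodic_label(mask: np.ndarray) -> Tuple[np.ndarray, int]:
    """Connected-component labelling with periodic wrap in all axes.

    Labels with ordinary 6-connectivity, then merges labels that touch
    across opposite faces using union–find.
    """
    labels, n = ndimage.label(mask)
    if n <= 1:
        return labels, n
    parent = list(range(n + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for axis in range(3):
        lo = np.take(labels, 0, axis=axis)
        hi = np.take(labels, -1, axis=axis)
        touch = (lo > 0) & (hi > 0)
        for a, b in zip(lo[touch].ravel(), hi[touch].ravel()):
            union(int(a), int(b))

    remap = np.zeros(n + 1, dtype=labels.dtype)
    next_label = 0
    for lab in range(1, n + 1):
        root = find(lab)
        if remap[root] == 0:
            next_label += 1
            remap[root] = next_label
        remap[lab] = remap[root]
    return remap[labels], next_label


def detect_cavity(
    frame: ParticleFrame,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    min_volume: float = DEFAULT_MIN_VOLUME,
) -> CavityField:
    """Locate empty regions of a frame with a probe-sphere occupancy grid.

    Parameters
    ----------
    frame : ParticleFrame
        Particle coordinates in a periodic orthorhombic box.
    grid_spacing : float
        Requested voxel edge in Å (the actual edge divides each box length
        exactly). The grid must resolve at least 3 voxels per box edge.
    probe_radius : float
        Radius (Å) of the probe sphere that must fit without touching a
        particle for space to count as empty; ~3 Å matches a water molecule.
    min_volume : float
        Smallest void volume (Å³) reported as a cavity; smaller pockets are
        thermal noise in a liquid-like configuration.

    Returns
    -------
    CavityField
        Deterministic for fixed inputs.
    """
    if not grid_spacing > 0:
        raise ValueError("grid_spacing must be > 0")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    lengths = frame.box.lengths
    n_vox = np.maximum(np.round(lengths / grid_spacing).astype(int), 1)
    if np.any(n_vox < 3):
        raise ValueError(
            f"grid too coarse: spacing {grid_spacing} Å gives {n_vox} voxels per edge; "
            "need at least 3"
        )
    spacing = lengths / n_vox
    origin = frame.box.origin

    coords = frame.wrapped_coordinates() - origin
    # guard against coordinates exactly at the upper boundary after wrapping
    coords = np.mod(coords, lengths)

    axes = [origin[d] + (np.arange(n_vox[d]) + 0.5) * spacing[d] for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3) - origin

    tree = cKDTree(coords, boxsize=lengths)
    dist_to_atoms, _ = tree.query(grid, workers=-1)
    dist_to_atoms = dist_to_atoms.reshape(tuple(n_vox))
    core = dist_to_atoms > probe_radius

    shape = tuple(n_vox)
    if not core.any():
        empty = np.zeros(shape, dtype=bool)
        return CavityField(
            origin=origin,
            spacing=spacing,
            core_mask=empty,
            cavity_mask=empty,
            signed_distance=np.full(shape, probe_radius),
            labels=np.zeros(shape, dtype=int),
            largest_label=0,
            probe_radius=probe_radius,
            min_volume=min_volume,
            secondary_volumes=[],
        )

    # periodic Euclidean distance to the core, via wrap-padded EDT
    pad = int(np.ceil(probe_radius / spacing.min())) + 2
    pad = min(pad, min(shape))  # never pad beyond one period
    padded = np.pad(~core, pad, mode="wrap")
    dist_to_core = ndimage.distance_transform_edt(padded, sampling=spacing)
    sl = tuple(slice(pad, pad + s) for s in shape)
    dist_to_core = dist_to_core[sl]

    cavity_mask = dist_to_core < probe_radius if probe_radius > 0 else core
    signed = dist_to_core - probe_radius

    labels, n_labels = _periodic_label(cavity_mask)
    voxel_volume = float(np.prod(spacing))
    largest_label = 0
    secondary: List[float] = []
    if n_labels:
        counts = np.bincount(labels.ravel(), minlength=n_labels + 1)[1:]
        volumes = counts * voxel_volume
        order = np.argsort(volumes)[::-1]
        above = [int(i) + 1 for i in order if volumes[i] >= min_volume]
        if above:
            largest_label = above[0]
            secondary = [float(volumes[l - 1]) for l in above[1:]]

    return CavityField(
        origin=origin,
        spacing=spacing,
        core_mask=core,
        cavity_mask=cavity_mask,
        signed_distance=signed,
        labels=labels,
        largest_label=largest_label,
        probe_radius=probe_radius,
        min_volume=min_volume,
        secondary_volumes=secondary,
    )


def _periodic_center_shift(mask: np.ndarray) -> Tuple[int, int, int]:
    """Roll offsets that align the largest empty gap of each axis with the boundary.

    After rolling, the mask does not touch the array faces on any axis that
    has at least one fully empty slab (the component may still percolate,
    which the caller detects).
    """
    shifts = []
    for axis in range(3):
        others = tuple(d for d in range(3) if d != axis)
        occ = mask.any(axis=others)
        n = occ.size
        if occ.all():
            shifts.append(0)
            continue
        # longest circular run of empty slabs, via the doubled array
        empty = np.concatenate([~occ, ~occ])
        best_len, best_start, run, start = 0, 0, 0, 0
        for i, e in enumerate(empty):
            if e:
                if run == 0:
                    start = i
                run += 1
                if run > best_len and start < n:
                    best_len, best_start = run, start
            else:
                run = 0
        gap_mid = (best_start + best_len // 2) % n
        shifts.append(-gap_mid % n)
    return tuple(shifts)


def _mesh_from_field(field: CavityField, smoothing: float = 3.0) -> trimesh.Trimesh:
    """Triangulate the largest cavity's surface from the signed-distance field.

    ``smoothing`` is the Gaussian width in Å applied to the field before
    marching cubes: the voxelised core boundary and the atomic granularity
    of the cavity wall make the raw distance field bumpy, which inflates
    the mesh area (staircase artifact).  A fixed physical width (default
    one probe radius, 3 Å) keeps the measurement convergent under grid
    refinement and shifts the level set of a 50 Å void by only
    ~σ²/R ≈ 0.2 Å, while restoring the area of a smooth cavity to within a
    percent at 2 Å spacing.
    """
    mask = field.labels == field.largest_label
    shift = _periodic_center_shift(mask)
    mask_c = np.roll(mask, shift, axis=(0, 1, 2))
    signed_c = np.roll(field.signed_distance, shift, axis=(0, 1, 2))
    # suppress other voids so only the selected component is meshed
    other = np.roll(field.cavity_mask & ~mask, shift, axis=(0, 1, 2))
    signed_c = np.where(other, field.probe_radius, signed_c)

    if (
        mask_c[0, :, :].any() or mask_c[-1, :, :].any()
        or mask_c[:, 0, :].any() or mask_c[:, -1, :].any()
        or mask_c[:, :, 0].any() or mask_c[:, :, -1].any()
    ):
        raise MeshError(
            "cavity spans the periodic box even after recentring; "
            "cannot build a closed surface mesh"
        )

    if smoothing > 0:
        sigma_vox = smoothing / field.spacing  # physical width -> per-axis voxels
        signed_c = ndimage.gaussian_filter(signed_c, sigma=sigma_vox, mode="wrap")
    if signed_c.min() >= 0.0:
        raise MeshError("cavity vanished under field smoothing; reduce smoothing or spacing")
    verts, faces, _, _ = marching_cubes(signed_c, level=0.0, spacing=tuple(field.spacing))
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if not mesh.is_watertight:
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        if not mesh.is_watertight:
            raise MeshError(
                f"cavity isosurface is not watertight "
                f"({len(mesh.faces)} faces, euler={mesh.euler_number})"
            )
    return mesh


def mesh_metrics(mesh: trimesh.Trimesh) -> CavityMetrics:
    """Cavity metrics of an arbitrary closed triangle mesh.

    Volume is the divergence-theorem sum over oriented triangles; the sign
    is discarded so either face orientation is accepted.
    """
    if len(mesh.faces) == 0:
        raise MeshError("empty mesh")
    if not mesh.is_watertight:
        raise MeshError(f"mesh is not watertight (euler={mesh.euler_number})")
    return CavityMetrics(volume_c=float(abs(mesh.volume)), area_c=float(mesh.area))


def cavity_metrics(
    cavity: Union[CavityField, trimesh.Trimesh], smoothing: float = 3.0
) -> CavityMetrics:
    """Measure volume, area, effective radius and sphericity of a cavity.

    Accepts the :class:`CavityField` returned by :func:`detect_cavity` (the
    largest void is meshed by marching cubes on its signed-distance field,
    Gaussian-smoothed by a ``smoothing`` Å width) or a ready-made closed
    triangle mesh.
    """
    if isinstance(cavity, trimesh.Trimesh):
        return mesh_metrics(cavity)
    if not cavity.has_cavity:
        raise MeshError("no cavity above the minimum-volume threshold")
    return mesh_metrics(_mesh_from_field(cavity, smoothing=smoothing))
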