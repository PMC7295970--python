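"""Synthetic particle and time-series generators with known ground truth.

Every generator emulates one statistical feature of an MD cavitation run —
a fluid box with a carved cavity, a trajectory following a prescribed
radius schedule, Brownian walkers with a known diffusion coefficient,
stationary Ornstein–Uhlenbeck stress fluctuations with a known Green–Kubo
viscosity, a noisy damped oscillation — and returns the generating
parameters alongside the data, so every downstream estimator can be tested
against an analytic expectation without running MD.

All generators are deterministic for a fixed seed.  Particles are
monodisperse pseudo-water beads (18 amu): the analysis stages consume only
positions, masses and per-atom stress, so molecular detail is unnecessary.
Fluid placement is rejection sampling with a minimum-distance criterion
(default 2.4 Å) emulating the correlation hole of a real liquid — ideal-gas
placement at 1.02 g/cm³ would leave ~2 % of space farther than a probe
radius from every bead, riddling a nominally homogeneous fluid with
probe-scale voids.  A jittered-lattice mode exists for exact-volume tests.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .bubble import RPSolution
from .constants import AMU_TO_G, BOLTZMANN, MPA_TO_ATM, PS_TO_S
from .frames import Box, ParticleFrame, ScalarTimeSeries, Trajectory

__all__ = [
    "ellipsoid_area",
    "ellipsoid_volume",
    "make_fluid_with_cavity",
    "make_growth_trajectory",
    "make_brownian_trajectory",
    "make_ou_stress_series",
    "make_damped_series",
]

DEFAULT_DENSITY = 1.02  # g/cm³, the water preset
DEFAULT_MASS = 18.0  # amu pseudo-water bead
DEFAULT_MIN_DISTANCE = 2.4  # Å, liquid correlation hole
DEFAULT_JITTER = 0.3  # Å thermal surface roughness between frames


def ellipsoid_volume(semi_axes: Sequence[float]) -> float:
    a, b, c = semi_axes
    return 4.0 / 3.0 * math.pi * a * b * c


def ellipsoid_area(semi_axes: Sequence[float]) -> float:
    """Surface area of an ellipsoid with the given semi-axes.

    Exact closed forms for spheres and spheroids; the Thomsen approximation
    (p = 1.6075, relative error ≲ 1e-3) for three distinct axes.
    """
    a, b, c = sorted(semi_axes, reverse=True)
    if math.isclose(a, b) and math.isclose(b, c):
        return 4.0 * math.pi * a * a
    if math.isclose(b, c):  # prolate: a > b = c
        e = math.sqrt(1.0 - (b / a) ** 2)
        return 2.0 * math.pi * b * b * (1.0 + (a / (b * e)) * math.asin(e))
    if math.isclose(a, b):  # oblate: a = b > c
        e = math.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * math.pi * a * a * (1.0 + ((1.0 - e * e) / e) * math.atanh(e))
    p = 1.6075
    ap, bp, cp = a**p, b**p, c**p
    return 4.0 * math.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / p)


def _min_distance_fill(
    rng: np.random.Generator,
    lengths: np.ndarray,
    n_target: int,
    min_distance: float,
    keep: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    """Sequential rejection sampling with a periodic minimum-distance core.

    ``keep`` is a vectorised predicate selecting admissible proposal points
    (e.g. outside the cavity).  Raises if the target count is infeasible.
    """
    accepted = np.empty((0, 3))
    stall = 0
    while accepted.shape[0] < n_target:
        need = n_target - accepted.shape[0]
        batch = rng.uniform(0.0, lengths, size=(max(2 * need, 1000), 3))
        batch = batch[keep(batch)]
        if batch.shape[0] and accepted.shape[0] and min_distance > 0:
            tree = cKDTree(accepted, boxsize=lengths)
            d, _ = tree.query(batch, workers=-1, distance_upper_bound=min_distance)
            batch = batch[np.isinf(d)]
        if batch.shape[0] and min_distance > 0:
            # greedy intra-batch thinning
            btree = cKDTree(batch, boxsize=lengths)
            drop = np.zeros(batch.shape[0], dtype=bool)
            for i, j in sorted(btree.query_pairs(min_distance)):
                if not drop[i]:
                    drop[j] = True
            batch = batch[~drop]
        if batch.shape[0] == 0:
            stall += 1
            if stall > 200:
                raise ValueError(
                    f"cannot place {n_target} particles at min_distance "
                    f"{min_distance} Å in this box: density infeasible"
                )
            continue
        stall = 0
        accepted = np.vstack([accepted, batch[:need]])
    return accepted


def _lattice_fill(
    lengths: np.ndarray,
    n_target: int,
    keep: Callable[[np.ndarray], np.ndarray],
    rng: Optional[np.random.Generator] = None,
    jitter: float = 0.0,
) -> np.ndarray:
    """Simple-cubic lattice placement (optionally jittered), for exact-volume tests."""
    n_cells = int(math.ceil(n_target ** (1.0 / 3.0)))
    while True:
        axes = [(np.arange(n_cells) + 0.5) * (lengths[d] / n_cells) for d in range(3)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        pts = pts[keep(pts)]
        if pts.shape[0] >= n_target:
            break
        n_cells += 1
    if jitter > 0 and rng is not None:
        pts = pts + rng.normal(0.0, jitter, size=pts.shape)
    if pts.shape[0] > n_target:
        # random subset, not a slab: a raveled-order trim would bias the density
        idx = rng.choice(pts.shape[0], size=n_target, replace=False) if rng is not None else np.linspace(0, pts.shape[0] - 1, n_target).round().astype(int)
        pts = pts[np.sort(idx)]
    return pts


def _particle_count(density: float, open_volume: float, mass: float) -> int:
    """Bead count realising a mass density (g/cm³) in an open volume (Å³)."""
    return int(round(density * open_volume / (mass * AMU_TO_G * 1e24)))


def _inside_ellipsoid(
    points: np.ndarray, center: np.ndarray, semi_axes: np.ndarray, lengths: np.ndarray
) -> np.ndarray:
    delta = points - center
    delta -= lengths * np.round(delta / lengths)  # minimum image
    return ((delta / semi_axes) ** 2).sum(axis=1) < 1.0


def make_fluid_with_cavity(
    box_lengths: Sequence[float],
    cavity_radius: float = 50.0,
    cavity_axes: Optional[Sequence[float]] = None,
    cavity_center: Optional[Sequence[float]] = None,
    density: float = DEFAULT_DENSITY,
    particle_mass: float = DEFAULT_MASS,
    min_distance: float = DEFAULT_MIN_DISTANCE,
    target_pressure: Optional[float] = None,
    lattice: bool = False,
    seed: int = 0,
) -> Tuple[ParticleFrame, Dict]:
    """Homogeneous fluid frame with a carved spherical or ellipsoidal cavity.

    Parameters
    ----------
    box_lengths : (3,) box edge lengths in Å.
    cavity_radius : float
        Sphere radius in Å; 0 for no cavity. Ignored if ``cavity_axes`` given.
    cavity_axes : (3,), optional
        Ellipsoid semi-axes in Å.
    cavity_center : (3,), optional
        Cavity centre; defaults to the box centre.
    density : float
        Target mass density in g/cm³ of the fluid outside the cavity.
    target_pressure : float, optional
        If given (MPa), isotropic per-atom stress and equal-share per-atom
        volumes are assigned so the virial global pressure recovers this
        value exactly (tension negative).
    lattice : bool
        Use simple-cubic placement instead of min-distance rejection
        sampling (exact-volume tests; beware Voronoi degeneracy).
    seed : int
        Random seed; identical seed ⇒ identical frame.

    Returns
    -------
    (ParticleFrame, dict)
        The frame and a ground-truth record of every generating parameter,
        including the analytic cavity volume and surface area.
    """
    lengths = np.asarray(box_lengths, dtype=float)
    if lengths.shape != (3,) or np.any(lengths <= 0):
        raise ValueError("box_lengths must be 3 positive edge lengths")
    box = Box.from_lengths(lengths)
    center = box.center() if cavity_center is None else np.asarray(cavity_center, float)
    if cavity_axes is not None:
        semi = np.asarray(cavity_axes, dtype=float)
    else:
        semi = np.full(3, float(cavity_radius))
    has_cavity = np.all(semi > 0)
    if has_cavity and np.any(2.0 * semi >= lengths):
        raise ValueError(f"cavity with semi-axes {semi} does not fit in box {lengths}")

    v_box = float(np.prod(lengths))
    v_cav = ellipsoid_volume(semi) if has_cavity else 0.0
    n = _particle_count(density, v_box - v_cav, particle_mass)
    if n < 1:
        raise ValueError("density/box too small: zero particles requested")

    if has_cavity:
        keep = lambda pts: ~_inside_ellipsoid(pts, center, semi, lengths)
    else:
        keep = lambda pts: np.ones(pts.shape[0], dtype=bool)

    rng = np.random.default_rng(seed)
    if lattice:
        coords = _lattice_fill(lengths, n, keep, rng, jitter=0.0)
    else:
        coords = _min_distance_fill(rng, lengths, n, min_distance, keep)

    masses = np.full(n, particle_mass)
    species = np.full(n, "W")
    stress = None
    volumes = None
    if target_pressure is not None:
        volumes = np.full(n, v_box / n)
        p_atm = target_pressure * MPA_TO_ATM
        stress = np.zeros((n, 6))
        stress[:, 0:3] = (p_atm * volumes)[:, None]

    frame = ParticleFrame(
        time=0.0,
        box=box,
        coordinates=coords,
        masses=masses,
        species=species,
        per_atom_stress=stress,
        per_atom_volume=volumes,
    )
    ground_truth = {
        "kind": "fluid_with_cavity",
        "seed": seed,
        "box_lengths_A": lengths.tolist(),
        "n_particles": n,
        "particle_mass_amu": particle_mass,
        "density_target_g_cm3": density,
        "density_realized_g_cm3": n * particle_mass * AMU_TO_G / ((v_box - v_cav) * 1e-24),
        "min_distance_A": min_distance,
        "lattice": lattice,
        "cavity_center_A": center.tolist(),
        "cavity_semi_axes_A": semi.tolist() if has_cavity else None,
        "cavity_volume_A3": v_cav,
        "cavity_area_A2": ellipsoid_area(semi) if has_cavity else 0.0,
        "target_pressure_MPa": target_pressure,
    }
    return frame, ground_truth


def _schedule_arrays(
    schedule: Union[RPSolution, Tuple[Sequence[float], Sequence[float]]],
) -> Tuple[np.ndarray, np.ndarray]:
    """Times (ps) and radii (Å) of a radius schedule or an RP solution (SI)."""
    if isinstance(schedule, RPSolution):
        return schedule.times / PS_TO_S, schedule.radius * 1e10
    times, radii = schedule
    return np.asarray(times, dtype=float), np.asarray(radii, dtype=float)


def make_growth_trajectory(
    box_lengths: Sequence[float],
    schedule: Union[RPSolution, Tuple[Sequence[float], Sequence[float]]],
    density: float = DEFAULT_DENSITY,
    particle_mass: float = DEFAULT_MASS,
    min_distance: float = DEFAULT_MIN_DISTANCE,
    jitter: float = DEFAULT_JITTER,
    max_frames: Optional[int] = None,
    seed: int = 0,
) -> Tuple[Trajectory, Dict]:
    """Trajectory whose central cavity follows a prescribed radius history.

    A single homogeneous base fluid is generated once; at each scheduled
    time the beads whose home positions fall inside the scheduled radius
    are removed (the cavity), and the survivors receive small Gaussian
    jitter (default σ = 0.3 Å) emulating a thermal interface.  Bead ids are
    their base-configuration indices, so identity is maintained and MSD is
    computable on the always-retained subset (``ground_truth["retained_ids"]``).

    ``schedule`` is either (times_ps, radii_A) arrays or an
    :class:`~nanocav.bubble.RPSolution` (SI, converted).  ``max_frames``
    subsamples a dense schedule evenly.
    """
    times, radii = _schedule_arrays(schedule)
    if times.size == 0:
        raise ValueError("empty radius schedule")
    if np.any(radii < 0):
        raise ValueError("scheduled radii must be non-negative")
    if max_frames is not None and times.size > max_frames:
        idx = np.unique(np.linspace(0, times.size - 1, max_frames).round().astype(int))
        times, radii = times[idx], radii[idx]

    lengths = np.asarray(box_lengths, dtype=float)
    if np.any(2.0 * radii.max() >= lengths):
        raise ValueError(f"scheduled radius {radii.max()} Å exceeds box {lengths}")
    box = Box.from_lengths(lengths)
    center = box.center()

    base, base_truth = make_fluid_with_cavity(
        box_lengths,
        cavity_radius=0.0,
        density=density,
        particle_mass=particle_mass,
        min_distance=min_distance,
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    coords0 = base.coordinates
    r_from_center = np.linalg.norm(coords0 - center, axis=1)

    frames = []
    for t, r in zip(times, radii):
        retained = r_from_center >= r
        pts = coords0[retained]
        if jitter > 0:
            pts = box.wrap(pts + rng.normal(0.0, jitter, size=pts.shape))
        frames.append(
            ParticleFrame(
                time=float(t),
                box=box,
                coordinates=pts,
                masses=base.masses[retained],
                species=base.species[retained],
                ids=np.nonzero(retained)[0] + 1,
            )
        )
    traj = Trajectory(frames, constant_identity=False)
    ground_truth = {
        "kind": "growth_trajectory",
        "seed": seed,
        "base": base_truth,
        "times_ps": times.tolist(),
        "radii_A": radii.tolist(),
        "jitter_A": jitter,
        "retained_ids": (np.nonzero(r_from_center >= radii.max())[0] + 1).tolist(),
    }
    return traj, ground_truth


def make_brownian_trajectory(
    n_walkers: int = 1000,
    n_steps: int = 1000,
    dt: float = 1.0,
    diffusion: float = 1e-9,
    box_length: float = 1000.0,
    particle_mass: float = DEFAULT_MASS,
    seed: int = 0,
) -> Tuple[Trajectory, Dict]:
    """Independent 3-D Brownian walkers with a known diffusion coefficient.

    Displacements per step are Gaussian with variance 2·D·dt per axis
    (``diffusion`` in m²/s, ``dt`` in ps).  Coordinates are stored
    unwrapped, so the MSD chain needs no image flags.
    """
    if n_walkers < 1 or n_steps < 2:
        raise ValueError("need at least 1 walker and 2 steps")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if diffusion < 0:
        raise ValueError("diffusion must be >= 0")
    rng = np.random.default_rng(seed)
    box = Box.from_lengths([box_length] * 3)
    start = rng.uniform(0.0, box_length, size=(n_walkers, 3))
    # variance 2 D dt per axis, in Å²: D[m²/s] -> Å²/ps is ×1e8
    sigma = math.sqrt(2.0 * diffusion * 1e8 * dt)
    steps = rng.normal(0.0, sigma, size=(n_steps - 1, n_walkers, 3)) if sigma > 0 else np.zeros((n_steps - 1, n_walkers, 3))
    paths = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)], axis=0)

    masses = np.full(n_walkers, particle_mass)
    species = np.full(n_walkers, "W")
    frames = [
        ParticleFrame(time=i * dt, box=box, coordinates=paths[i], masses=masses, species=species)
        for i in range(n_steps)
    ]
    ground_truth = {
        "kind": "brownian",
        "seed": seed,
        "n_walkers": n_walkers,
        "n_steps": n_steps,
        "dt_ps": dt,
        "diffusion_m2_s": diffusion,
        "step_sigma_A": sigma,
    }
    return Trajectory(frames), ground_truth


def make_ou_stress_series(
    n_steps: int = 100_000,
    dt: float = 0.1,
    correlation_time: float = 1.0,
    stress_std: float = 1e6,
    n_components: int = 3,
    volume: float = 1e-24,
    temperature: float = 300.0,
    seed: int = 0,
) -> Tuple[list, Dict]:
    """Stationary Ornstein–Uhlenbeck off-diagonal stress components.

    Exact discretisation: x_{k+1} = x_k·e^(−dt/τ) + s·√(1−e^(−2dt/τ))·ξ,
    started from the stationary distribution, so every component has
    variance s² and autocorrelation s²·e^(−t/τ) at any dt.  The implied
    Green–Kubo viscosity (V/kB·T)·s²·τ is recorded in the ground truth;
    note it depends on τ only through the product s²·τ (white-noise limit).

    Times are ps, stress values Pa, ``volume`` m³.
    """
    if n_steps < 2 or dt <= 0 or correlation_time <= 0:
        raise ValueError("n_steps >= 2, dt > 0 and correlation_time > 0 required")
    rng = np.random.default_rng(seed)
    phi = math.exp(-dt / correlation_time)
    innov = stress_std * math.sqrt(1.0 - phi * phi)
    times = np.arange(n_steps) * dt
    series = []
    names = ["Pxy", "Pxz", "Pyz", "Pxy2", "Pxz2", "Pyz2"]
    for c in range(n_components):
        x = np.empty(n_steps)
        x[0] = rng.normal(0.0, stress_std)
        noise = rng.normal(0.0, innov, size=n_steps - 1)
        for k in range(1, n_steps):
            x[k] = phi * x[k - 1] + noise[k - 1]
        series.append(ScalarTimeSeries(times, x, unit="Pa", name=names[c % len(names)]))
    ground_truth = {
        "kind": "ou_stress",
        "seed": seed,
        "n_steps": n_steps,
        "dt_ps": dt,
        "correlation_time_ps": correlation_time,
        "stress_std_Pa": stress_std,
        "n_components": n_components,
        "volume_m3": volume,
        "temperature_K": temperature,
        "viscosity_Pa_s": volume / (BOLTZMANN * temperature) * stress_std**2 * correlation_time * PS_TO_S,
    }
    return series, ground_truth


def make_damped_series(
    n_steps: int = 2000,
    dt: float = 0.01,
    amplitude: float = 1.0,
    decay_rate: float = 1.39e10,
    frequency: float = 0.0,
    offset: float = 0.0,
    noise_std: float = 0.0,
    seed: int = 0,
) -> Tuple[ScalarTimeSeries, Dict]:
    """Exponentially damped (optionally oscillating) series with noise.

    y(t) = amplitude·e^(−λ·t)·cos(2π·f·t) + offset + Gaussian noise, with
    ``decay_rate`` λ in s⁻¹ (the volume-relaxation rate b/m scale,
    ~1.4e10 s⁻¹ for a 95 Å water bubble), ``frequency`` in THz (1/ps) and
    times in ps.
    """
    if n_steps < 2 or dt <= 0:
        raise ValueError("n_steps >= 2 and dt > 0 required")
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps) * dt
    y = amplitude * np.exp(-decay_rate * t * PS_TO_S) * np.cos(2.0 * math.pi * frequency * t) + offset
    if noise_std > 0:
        y = y + rng.normal(0.0, noise_std, size=n_steps)
    series = ScalarTimeSeries(t, y, unit="", name="damped")
    ground_truth = {
        "kind": "damped_series",
        "seed": seed,
        "n_steps": n_steps,
        "dt_ps": dt,
        "amplitude": amplitude,
        "decay_rate_per_s": decay_rate,
        "frequency_THz": frequency,
        "offset": offset,
        "noise_std": noise_std,
    }
    return series, ground_truth
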