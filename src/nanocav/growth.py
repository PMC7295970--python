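"""Per-frame bubble-growth analysis of a trajectory.

Applies the virial pressure, cavity detection/metrics and cavity-excluded
density to every frame of a trajectory and returns aligned scalar series
(pressure, cavity radius, sphericity, density, cavity volume) suitable for
inspecting the growth stages: slow surface-tension-limited growth, the
sharp threshold-pressure excursion, and the stabilised regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cavity import (
    DEFAULT_GRID_SPACING,
    DEFAULT_MIN_VOLUME,
    DEFAULT_PROBE_RADIUS,
    cavity_metrics,
    detect_cavity,
)
from .frames import ScalarTimeSeries, Trajectory
from .pressure import ThresholdResult, density_excluding_cavity, global_pressure, threshold_pressure

__all__ = ["GrowthResult", "growth_analysis"]


@dataclass
class GrowthResult:
    """Aligned per-frame series from :func:`growth_analysis`.

    ``pressure`` is ``None`` when the trajectory carries no per-atom
    stress.  ``radius`` is the effective radius (3·V_c/4π)^(1/3) of each
    frame's largest cavity (0 where no cavity was found); ``sphericity`` is
    NaN there.  ``threshold`` summarises the smoothed pressure minimum.
    """

    radius: ScalarTimeSeries
    cavity_volume: ScalarTimeSeries
    sphericity: ScalarTimeSeries
    density: ScalarTimeSeries
    secondary_voids: ScalarTimeSeries
    pressure: Optional[ScalarTimeSeries] = None
    threshold: Optional[ThresholdResult] = None


def growth_analysis(
    traj: Trajectory,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    min_volume: float = DEFAULT_MIN_VOLUME,
    smoothing_window: float = 1.0,
    pressure_selection=None,
) -> GrowthResult:
    """Run the full growth-analysis chain on every frame.

    Failures inside a frame are re-raised with the frame index attached.
    Threshold extraction is attempted only when a pressure series exists
    and is long enough for the smoothing window.
    """
    times = traj.times
    has_stress = all(f.per_atom_stress is not None and f.per_atom_volume is not None for f in traj)

    pressures = []
    volumes = []
    radii = []
    spher = []
    dens = []
    n_secondary = []
    for i, frame in enumerate(traj):
        try:
            field = detect_cavity(frame, grid_spacing, probe_radius, min_volume)
            if field.has_cavity:
                m = cavity_metrics(field)
                volumes.append(m.volume_c)
                radii.append(m.effective_radius)
                spher.append(m.sphericity)
                v_excl = m.volume_c
            else:
                volumes.append(0.0)
                radii.append(0.0)
                spher.append(np.nan)
                v_excl = 0.0
            n_secondary.append(field.secondary_void_count)
            dens.append(density_excluding_cavity(frame, v_excl))
            if has_stress:
                pressures.append(global_pressure(frame, pressure_selection))
        except Exception as exc:
            raise RuntimeError(f"growth analysis failed at frame {i} (t={frame.time} ps): {exc}") from exc

    result = GrowthResult(
        radius=ScalarTimeSeries(times, np.array(radii), unit="A", name="cavity_radius"),
        cavity_volume=ScalarTimeSeries(times, np.array(volumes), unit="A^3", name="cavity_volume"),
        sphericity=ScalarTimeSeries(times, np.array(spher), unit="", name="sphericity"),
        density=ScalarTimeSeries(times, np.array(dens), unit="g/cm^3", name="density"),
        secondary_voids=ScalarTimeSeries(
            times, np.array(n_secondary, dtype=float), unit="count", name="secondary_voids"
        ),
    )
    if has_stress:
        result.pressure = ScalarTimeSeries(times, np.array(pressures), unit="MPa", name="pressure")
        if len(traj) >= 3:
            try:
                result.threshold = threshold_pressure(result.pressure, smoothing_window)
            except ValueError:
                result.threshold = None
    return result
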