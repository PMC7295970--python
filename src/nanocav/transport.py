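"""Transport estimators: mean-square displacement, diffusion, Green–Kubo viscosity.

MSD uses every available time origin per lag (the FFT decomposition of the
origin-averaged sum, O(T log T) per particle).  The 3-D diffusion
coefficient is one sixth of the MSD slope over a configurable fit window.
Shear viscosity follows the Green–Kubo relation

    η = (V / kB·T) ∫₀^cutoff ⟨P_offdiag(0) · P_offdiag(t)⟩ dt,

with the autocorrelation averaged over the independent off-diagonal
pressure components and over time origins, trapezoidal integration, and a
block-averaged standard error.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .constants import A2_PER_PS_TO_M2_PER_S, BOLTZMANN
from .frames import ScalarTimeSeries, TransportEstimate, Trajectory

__all__ = ["msd", "diffusion_coefficient", "green_kubo_viscosity", "autocorrelation"]


class UnwrapError(ValueError):
    """Raised when coordinates are wrapped and no image flags allow unwrapping."""


def _stacked_coordinates(traj: Trajectory, selection: Optional[np.ndarray]) -> np.ndarray:
    """(T, N, 3) unwrapped coordinates of the selected common particles."""
    ids = traj.common_ids()
    if selection is not None:
        selection = np.asarray(selection)
        if selection.dtype == bool:
            raise ValueError("selection must be an array of particle ids")
        ids = np.intersect1d(ids, selection)
    if ids.size == 0:
        raise ValueError("no particles common to all frames in the selection")
    coords = np.empty((len(traj), ids.size, 3))
    for i, frame in enumerate(traj):
        order = {pid: j for j, pid in enumerate(frame.ids)}
        rows = np.array([order[pid] for pid in ids])
        coords[i] = frame.unwrapped_coordinates()[rows]
    # wrapped data without image flags shows box-scale jumps between frames
    lengths = traj[0].box.lengths
    jumps = np.abs(np.diff(coords, axis=0))
    if np.any(jumps > 0.5 * lengths):
        if any(f.images is None for f in traj):
            raise UnwrapError(
                "displacements exceed half the box but no periodic image flags are "
                "present; provide unwrapped coordinates or image flags"
            )
    return coords


def _msd_fft_single(r: np.ndarray) -> np.ndarray:
    """All-origin MSD of one (T, 3) path via the FFT decomposition."""
    t_len = r.shape[0]
    nfft = 1 << (2 * t_len - 1).bit_length()
    sq = (r * r).sum(axis=1)
    # S2(k) = sum_t r(t)·r(t+k), from the autocorrelation of each coordinate
    fts = np.fft.rfft(r, n=nfft, axis=0)
    s2 = np.fft.irfft((fts * fts.conj()).real.sum(axis=1), n=nfft)[:t_len]
    # S1(k) = sum over valid origins of |r(t)|² + |r(t+k)|², by running sums
    sumsq = 2.0 * sq.sum()
    s1 = np.empty(t_len)
    s1[0] = sumsq
    for k in range(1, t_len):
        sumsq -= sq[k - 1] + sq[t_len - k]
        s1[k] = sumsq
    counts = t_len - np.arange(t_len)
    return (s1 - 2.0 * s2) / counts


def msd(
    traj: Trajectory,
    selection: Optional[np.ndarray] = None,
    max_lag: Optional[float] = None,
) -> ScalarTimeSeries:
    """Origin-averaged mean-square displacement (Å²) versus lag (ps).

    Parameters
    ----------
    traj : Trajectory
        Uniformly sampled; at least 2 frames.  Coordinates must be
        unwrapped, or carry image flags.
    selection : array of particle ids, optional
        Restrict to a subset (e.g. water of the gel model, excluding the
        collagen network).
    max_lag : float, optional
        Longest reported lag in ps; default half the trajectory span
        (longer lags average too few origins to be reliable).
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 frames")
    times = traj.times
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("MSD requires uniform frame spacing")
    dt = float(dt[0])
    coords = _stacked_coordinates(traj, selection)
    t_len, n, _ = coords.shape

    acc = np.zeros(t_len)
    for j in range(n):
        acc += _msd_fft_single(coords[:, j, :])
    values = acc / n

    span = times[-1] - times[0]
    lag_cap = 0.5 * span if max_lag is None else max_lag
    n_lag = min(t_len - 1, max(1, int(round(lag_cap / dt))))
    lags = np.arange(n_lag + 1) * dt
    return ScalarTimeSeries(lags, values[: n_lag + 1], unit="A^2", name="msd")


def diffusion_coefficient(
    msd_series: ScalarTimeSeries,
    fit_window: Tuple[float, float] = (0.2, 0.8),
) -> TransportEstimate:
    """Diffusion coefficient (m²/s) from the MSD slope.

    For 3-D diffusion MSD = 6·D·t, so D is one sixth of the least-squares
    slope of MSD versus lag over the fit window (fractions of the maximum
    lag, default 20–80 %).  The log–log slope α over the same window is a
    fit diagnostic: α ≈ 1 is diffusive, α ≈ 2 ballistic; |α − 1| > 0.3 sets
    the ``non_diffusive`` flag.
    """
    lo, hi = fit_window
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("fit_window must satisfy 0 <= lo < hi <= 1")
    t = msd_series.times
    y = msd_series.values
    t_max = t[-1]
    mask = (t >= lo * t_max) & (t <= hi * t_max) & (t > 0)
    if mask.sum() < 2:
        raise ValueError("fit window contains fewer than 2 samples")
    tf, yf = t[mask], y[mask]
    (slope, intercept), cov = np.polyfit(tf, yf, 1, cov=True)
    slope_se = float(np.sqrt(cov[0, 0]))

    positive = yf > 0
    if positive.sum() >= 2 and np.any(yf[positive] > 0):
        alpha = float(np.polyfit(np.log(tf[positive]), np.log(yf[positive]), 1)[0])
    else:
        alpha = float("nan")

    d_value = slope / 6.0 * A2_PER_PS_TO_M2_PER_S
    d_se = slope_se / 6.0 * A2_PER_PS_TO_M2_PER_S
    return TransportEstimate(
        value=float(d_value),
        standard_error=d_se,
        unit="m^2/s",
        metadata={
            "slope_A2_per_ps": float(slope),
            "intercept_A2": float(intercept),
            "fit_window": (float(lo), float(hi)),
            "loglog_exponent": alpha,
            "non_diffusive": bool(not np.isnan(alpha) and abs(alpha - 1.0) > 0.3),
        },
    )


def autocorrelation(x: np.ndarray) -> np.ndarray:
    """Unbiased origin-averaged autocorrelation ⟨x(0)x(k)⟩ of a 1-D series."""
    x = np.asarray(x, dtype=float)
    n = x.size
    nfft = 1 << (2 * n - 1).bit_length()
    ft = np.fft.rfft(x, n=nfft)
    acf = np.fft.irfft(ft * ft.conj(), n=nfft)[:n]
    return acf / (n - np.arange(n))


def _gk_integral(components: np.ndarray, n_cut: int, dt: float) -> float:
    """Component-averaged ACF integrated to the cutoff (trapezoid)."""
    acf = np.mean([autocorrelation(c)[: n_cut + 1] for c in components], axis=0)
    return float(np.trapezoid(acf, dx=dt))


def green_kubo_viscosity(
    stress_components: Sequence[np.ndarray],
    volume: float,
    temperature: float,
    dt: float,
    cutoff: Optional[float] = None,
    n_blocks: int = 5,
) -> TransportEstimate:
    """Shear viscosity (Pa·s) from off-diagonal pressure fluctuations.

    Parameters
    ----------
    stress_components : sequence of 1-D arrays
        Stationary off-diagonal pressure components (Pa), e.g. Pxy, Pxz,
        Pyz, equal length, uniformly sampled.
    volume : float
        System volume in m³.
    temperature : float
        K.
    dt : float
        Sampling interval in seconds.
    cutoff : float, optional
        Upper integration limit in seconds.  Default: 10× the integrated
        autocorrelation time estimated from the data (the ACF integral to
        its first zero crossing, divided by the variance).  The series must
        be at least 10× the cutoff long.
    n_blocks : int
        Contiguous blocks for the standard error (≥ 5 recommended).

    Returns
    -------
    TransportEstimate
        η with a block-averaged standard error; metadata records the cutoff
        and blocking used.
    """
    comps = [np.asarray(c, dtype=float) for c in stress_components]
    if not comps:
        raise ValueError("need at least one stress component")
    n = comps[0].size
    if any(c.size != n for c in comps):
        raise ValueError("all stress components must have equal length")
    if n < 4:
        raise ValueError("series too short")
    if volume <= 0 or temperature <= 0 or dt <= 0:
        raise ValueError("volume, temperature and dt must be positive")

    arr = np.vstack(comps)
    variance = float(np.mean(arr * arr))
    duration = (n - 1) * dt

    if variance == 0.0:
        return TransportEstimate(0.0, 0.0, "Pa*s", {"cutoff_s": 0.0, "n_blocks": 0})

    if cutoff is None:
        acf = np.mean([autocorrelation(c) for c in arr], axis=0)
        below = np.nonzero(acf <= 0)[0]
        i_zero = int(below[0]) if below.size else acf.size
        tau = float(np.trapezoid(acf[:i_zero], dx=dt)) / acf[0]
        cutoff = 10.0 * max(tau, dt)
    n_cut = int(round(cutoff / dt))
    if n_cut >= n:
        raise ValueError(f"cutoff {cutoff} s >= series duration {duration} s")
    if n < 10 * n_cut:
        raise ValueError(
            f"series length {n} shorter than 10x the cutoff ({10 * n_cut} samples); "
            "the autocorrelation estimate would be unreliable"
        )

    prefactor = volume / (BOLTZMANN * temperature)
    eta = prefactor * _gk_integral(arr, n_cut, dt)

    block_len = n // n_blocks
    block_etas = []
    if block_len > n_cut:
        for b in range(n_blocks):
            seg = arr[:, b * block_len : (b + 1) * block_len]
            block_etas.append(prefactor * _gk_integral(seg, n_cut, dt))
    if len(block_etas) >= 2:
        se = float(np.std(block_etas, ddof=1) / np.sqrt(len(block_etas)))
    else:
        se = 0.0

    return TransportEstimate(
        value=float(eta),
        standard_error=se,
        unit="Pa*s",
        metadata={
            "cutoff_s": float(n_cut * dt),
            "n_blocks": len(block_etas),
            "n_components": len(comps),
            "stress_variance_Pa2": variance,
        },
    )
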