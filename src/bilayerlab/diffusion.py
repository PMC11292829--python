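"""Mean-squared displacement and Einstein-relation diffusion coefficients.

The MSD is averaged over all sliding time origins (FFT-based, so long
trajectories stay cheap) and over molecules, whose mass-weighted centres are
the diffusing entities. Lags are kept to a fraction of the trajectory
(default 25%) because long lags average over few independent origins and
dominate the noise. D comes from a through-origin least-squares line
(MSD(0) = 0 exactly) on a window of the curve, default 10–50% of the
maximum lag: D = slope / (2d), converted Å²/ps → m²/s. A fit with R² < 0.9
attaches a low-linearity warning (ballistic or confined motion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    ANG2_PER_PS_TO_M2_PER_S,
    Selection,
    Trajectory,
    centers_of_mass,
    minimum_image_displacement,
    molecule_index_groups,
)
from .errors import ParameterError, TrajectoryInconsistencyError, UnwrapAmbiguityWarning

MODES = {"z": (2,), "xy": (0, 1), "xyz": (0, 1, 2)}


@dataclass
class MsdCurve:
    lags: np.ndarray  # (L,) ps, starting at 0
    msd: np.ndarray  # (L,) Å²
    d: int  # dimensionality (1, 2 or 3)
    mode: str  # "z", "xy" or "xyz"
    n_molecules: int
    D: float | None = None  # m²/s, set by fit_diffusion
    fit_window: tuple[float, float] | None = None
    r_squared: float | None = None


def unwrap_trajectory(
    traj: Trajectory, selection: Selection | None = None
) -> np.ndarray:
    """Continuous coordinates: periodic jumps removed by accumulating
    nearest-image increments. Requires true per-frame displacements below
    half the box per axis; a wrapped increment beyond 45% of the box length
    triggers an ambiguity warning with the frame index."""
    box = traj.constant_box()
    idx = selection.indices if selection is not None else np.arange(traj.n_atoms)
    pos = traj.positions[:, idx, :]
    steps = minimum_image_displacement(pos[:-1], pos[1:], box)
    big = np.abs(steps) > 0.45 * box
    if big.any():
        frames = np.unique(np.nonzero(big)[0] + 1)
        warnings.warn(
            f"unwrap ambiguity: near-half-box steps at frame(s) {frames[:10].tolist()}"
            " — sampling interval may be too coarse",
            UnwrapAmbiguityWarning,
            stacklevel=2,
        )
    out = np.empty_like(pos)
    out[0] = pos[0]
    np.cumsum(steps, axis=0, out=steps)
    out[1:] = pos[0] + steps
    return out


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """Sliding-origin MSD of one coordinate series per column; x is (N, M)."""
    n = x.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:n].real
    sq = x * x
    # S1(τ) = Σ_t (x_t² + x_{t+τ}²) over valid origins, via suffix/prefix sums
    css = np.concatenate([np.zeros((1, x.shape[1])), np.cumsum(sq, axis=0)])
    total = css[-1]
    tau = np.arange(n)
    # Σ_{t<n-τ} x_t² + Σ_{t>=τ} x_t²
    s1 = css[n - tau] + (total - css[tau])
    counts = (n - tau)[:, None]
    return s1 / counts - 2.0 * acf / counts


def msd(
    unwrapped: np.ndarray,
    times: np.ndarray,
    topology=None,
    selection: Selection | None = None,
    mode: str = "xyz",
    max_lag_fraction: float = 0.25,
) -> MsdCurve:
    """MSD(τ) averaged over molecules and all time origins.

    `unwrapped` is (n_frames, n_atoms, 3) continuous coordinates (matching
    the full topology, or pre-sliced with topology=None, in which case each
    column is treated as one particle). With a topology, particles are the
    mass-weighted molecular centres of the selected atoms.
    """
    times = np.asarray(times, dtype=float)
    if unwrapped.ndim != 3 or len(times) != unwrapped.shape[0]:
        raise ParameterError("unwrapped must be (n_frames, n_particles, 3)")
    if unwrapped.shape[0] < 2:
        raise ParameterError("MSD needs at least 2 frames")
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=0.0):
        raise TrajectoryInconsistencyError(
            "MSD requires a uniform time step; resample the trajectory first"
        )
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {sorted(MODES)}")
    if not 0.0 < max_lag_fraction <= 1.0:
        raise ParameterError("max_lag_fraction must be in (0, 1]")

    if topology is not None:
        idx = selection.indices if selection is not None else np.arange(
            unwrapped.shape[1]
        )
        groups = list(molecule_index_groups(topology, idx).values())
        series = centers_of_mass(unwrapped, topology, groups)  # (F, M, 3)
    else:
        series = unwrapped

    comps = MODES[mode]
    n = series.shape[0]
    max_lag = max(1, int(np.floor(max_lag_fraction * (n - 1))))
    total = np.zeros(n)
    for c in comps:
        total += _msd_fft_1d(series[:, :, c]).mean(axis=1)
    lags = (times - times[0])[: max_lag + 1]
    curve = total[: max_lag + 1]
    curve[0] = 0.0  # exact by definition
    return MsdCurve(
        lags=lags,
        msd=curve,
        d=len(comps),
        mode=mode,
        n_molecules=series.shape[1],
    )


def fit_diffusion(
    curve: MsdCurve, window: tuple[float, float] = (0.1, 0.5)
) -> MsdCurve:
    """Einstein-relation fit: D = slope/(2d) on the windowed MSD curve.

    The fit is a through-origin least-squares line (the MSD vanishes at zero
    lag by definition); the window is a fraction of the maximum lag. Returns
    the curve with D (m²/s), the window and R² filled in; R² < 0.9 raises a
    low-linearity warning but still reports the fit.
    """
    lo, hi = window
    if not 0.0 <= lo < hi <= 1.0:
        raise ParameterError("fit window must satisfy 0 <= lo < hi <= 1")
    tmax = curve.lags[-1]
    mask = (curve.lags >= lo * tmax) & (curve.lags <= hi * tmax) & (curve.lags > 0)
    if mask.sum() < 5:
        raise ParameterError(
            f"fit window contains {int(mask.sum())} lags; need at least 5"
        )
    t = curve.lags[mask]
    y = curve.msd[mask]
    slope = float((t * y).sum() / (t * t).sum())
    ss_res = float(((y - slope * t) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    D = slope / (2.0 * curve.d) * ANG2_PER_PS_TO_M2_PER_S
    if r2 < 0.9:
        warnings.warn(
            f"MSD fit R² = {r2:.3f} < 0.9: curve is not linear in the window "
            "(ballistic, confined, or undersampled motion?)",
            stacklevel=2,
        )
    curve.D = float(D)
    curve.fit_window = (lo, hi)
    curve.r_squared = float(r2)
    return curve


def diffusion_coefficient(
    traj: Trajectory,
    selection: Selection | None = None,
    mode: str = "xyz",
    max_lag_fraction: float = 0.25,
    window: tuple[float, float] = (0.1, 0.5),
) -> MsdCurve:
    """Unwrap → molecular-COM MSD → Einstein fit, in one call."""
    unwrapped = unwrap_trajectory(traj, selection)
    topo = traj.topology
    if selection is not None:
        topo = topo.iloc[selection.indices].reset_index(drop=True)
    curve = msd(
        unwrapped,
        traj.times,
        topology=topo,
        selection=None,
        mode=mode,
        max_lag_fraction=max_lag_fraction,
    )
    return fit_diffusion(curve, window=window)
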