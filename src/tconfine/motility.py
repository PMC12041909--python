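"""Cell and molecule motility from tracked positions.

The central quantity is the pooled mean squared displacement (MSD): all
trajectories recorded under one condition are pooled and, for each lag
time t, the squared displacement is averaged over every (overlapping)
pair of positions that lag apart.  The pooled curve is fitted with a
model that accounts for both random and directed motion,

    MSD(t) = 4 D t + V² t² + 4 PA²,

where D is the diffusion constant (μm²/s), V the global movement speed
(μm/s) and PA the positional accuracy (μm) of the tracking.  Because the
model is linear in (D, V², PA²) with non-negativity constraints, the fit
is a weighted non-negative least squares problem and has no
initialisation or convergence concerns.

Uncertainties are obtained by bootstrapping whole trajectories: tracks
are resampled with replacement, re-pooled and re-fitted; the standard
deviation over replicates is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "MSDCurve",
    "MotilityFit",
    "CellKinematics",
    "pooled_msd",
    "fit_motility",
    "bootstrap_fit",
    "cell_kinematics",
]


@dataclass
class MSDCurve:
    """Pooled MSD versus lag time."""

    lag_s: np.ndarray     # strictly increasing lag times
    msd: np.ndarray       # μm²
    n_pairs: np.ndarray   # displacement pairs contributing per lag

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lag_s, "msd_um2": self.msd, "n_pairs": self.n_pairs})


@dataclass
class MotilityFit:
    """Parameters of the diffusion + directed-motion MSD model."""

    d: float                      # μm²/s
    v: float                      # μm/s
    pa: float                     # μm
    residual: float               # weighted RMS residual, μm²
    n_tracks: int
    d_sd: float | None = None     # bootstrap SDs, populated by bootstrap_fit
    v_sd: float | None = None
    pa_sd: float | None = None
    low_sample: bool = False


@dataclass
class CellKinematics:
    """Per-cell trajectory shape descriptors."""

    local_velocity: float          # μm/min, windowed mean speed
    persistence: float             # net displacement / path length, in [0, 1]


def _track_positions(tracks: pd.DataFrame) -> list[np.ndarray]:
    """Split a track table into per-track position arrays ordered by frame."""
    out = []
    for _, g in tracks.groupby("particle", sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        if len(frames) > 1 and (np.any(np.diff(frames) <= 0)):
            raise ValueError("track frames must be strictly increasing per id")
        out.append(g[["x_um", "y_um"]].to_numpy(dtype=float))
    return out


def _lag_sums(positions: list[np.ndarray], max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-track sums of squared displacements and pair counts per lag.

    Returns arrays of shape (n_tracks, max_lag); lag index ℓ corresponds
    to a lag of ℓ+1 frames.  Overlapping pairs are used.
    """
    n = len(positions)
    s = np.zeros((n, max_lag))
    c = np.zeros((n, max_lag))
    for i, pos in enumerate(positions):
        for lag in range(1, min(max_lag, len(pos) - 1) + 1):
            d2 = np.sum((pos[lag:] - pos[:-lag]) ** 2, axis=1)
            s[i, lag - 1] = d2.sum()
            c[i, lag - 1] = d2.size
    return s, c


def default_max_lag(tracks: pd.DataFrame, fraction: float = 0.25) -> int:
    """Default fit range: ``fraction`` of the median track length in frames."""
    lengths = tracks.groupby("particle").size().to_numpy()
    return max(2, int(np.floor(np.median(lengths) * fraction)))


def pooled_msd(tracks: pd.DataFrame, frame_interval: float, max_lag: int) -> MSDCurve:
    """Pool all trajectories and compute the ensemble MSD curve.

    ``tracks`` needs columns ``particle``, ``frame``, ``x_um``, ``y_um``.
    Lags with no contributing pair are dropped (so requesting a lag range
    longer than the longest track truncates the curve).
    """
    positions = _track_positions(tracks)
    if not positions or all(len(p) < 2 for p in positions):
        raise ValueError("need at least one track with two or more points")
    longest = max(len(p) for p in positions) - 1
    if max_lag > longest:
        max_lag = longest
    s, c = _lag_sums(positions, max_lag)
    n_pairs = c.sum(axis=0)
    keep = n_pairs > 0
    lags = np.arange(1, max_lag + 1)[keep]
    msd = s.sum(axis=0)[keep] / n_pairs[keep]
    return MSDCurve(lag_s=lags * frame_interval, msd=msd, n_pairs=n_pairs[keep])


def fit_motility(msd: MSDCurve, n_tracks: int = 0) -> MotilityFit:
    """Fit MSD(t) = 4Dt + V²t² + 4PA² with non-negativity constraints.

    The model is linear in θ = (D, V², PA²), θ ≥ 0, so a weighted
    non-negative least squares solve is exact.  Weights are proportional
    to the number of displacement pairs per lag.
    """
    t = np.asarray(msd.lag_s, dtype=float)
    y = np.asarray(msd.msd, dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct lags to fit D, V and PA")
    w = np.sqrt(np.asarray(msd.n_pairs, dtype=float))
    design = np.column_stack([4.0 * t, t**2, np.full_like(t, 4.0)])
    theta, rnorm = nnls(design * w[:, None], y * w)
    d, v2, pa2 = theta
    return MotilityFit(
        d=d,
        v=float(np.sqrt(v2)),
        pa=float(np.sqrt(pa2)),
        residual=float(rnorm / np.sqrt(w.size)),
        n_tracks=n_tracks,
    )


def bootstrap_fit(
    tracks: pd.DataFrame,
    frame_interval: float,
    n_boot: int = 1000,
    seed: int = 0,
    max_lag: int | None = None,
) -> MotilityFit:
    """Point fit plus bootstrap SDs for (D, V, PA).

    The resampling unit is the trajectory: each replicate draws n tracks
    with replacement, re-pools the MSD and re-fits.  Deterministic for a
    given seed.  Fewer than 5 tracks sets ``low_sample``.
    """
    positions = _track_positions(tracks)
    n = len(positions)
    if max_lag is None:
        max_lag = default_max_lag(tracks)
    longest = max(len(p) for p in positions) - 1
    max_lag = min(max_lag, longest)
    s, c = _lag_sums(positions, max_lag)

    curve = pooled_msd(tracks, frame_interval, max_lag)
    fit = fit_motility(curve, n_tracks=n)
    fit.low_sample = n < 5

    rng = np.random.default_rng(seed)
    # resampling with replacement == multinomial weights over tracks
    weights = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)
    s_b = weights @ s       # (n_boot, max_lag)
    c_b = weights @ c
    t_all = np.arange(1, max_lag + 1) * frame_interval
    samples = np.empty((n_boot, 3))
    for i in range(n_boot):
        keep = c_b[i] > 0
        t = t_all[keep]
        if len(np.unique(t)) < 3:
            samples[i] = np.nan
            continue
        y = s_b[i, keep] / c_b[i, keep]
        w = np.sqrt(c_b[i, keep])
        design = np.column_stack([4.0 * t, t**2, np.full_like(t, 4.0)])
        theta, _ = nnls(design * w[:, None], y * w)
        samples[i] = theta[0], np.sqrt(theta[1]), np.sqrt(theta[2])
    fit.d_sd, fit.v_sd, fit.pa_sd = np.nanstd(samples, axis=0)
    return fit


def cell_kinematics(
    positions: np.ndarray, frame_interval: float, window: int = 3
) -> CellKinematics:
    """Average local velocity and directional persistence of one track.

    Local velocity is the frame-to-frame speed smoothed with a sliding
    mean of ``window`` frames, averaged over the track and reported in
    μm/min.  Directional persistence is the ratio of net displacement to
    path length: 1 for straight motion, → 0 for closed paths.
    """
    pos = np.asarray(positions, dtype=float)
    if len(pos) < 2:
        raise ValueError("track must have at least 2 points")
    if not 2 <= window <= len(pos):
        raise ValueError("window must satisfy 2 <= window <= track length")
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    speeds = step / frame_interval
    if len(speeds) >= window:
        kernel = np.full(window, 1.0 / window)
        smoothed = np.convolve(speeds, kernel, mode="valid")
    else:
        smoothed = speeds
    velocity = float(np.mean(smoothed)) * 60.0  # μm/s → μm/min
    path = float(step.sum())
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    persistence = net / path if path > 0 else 0.0
    return CellKinematics(local_velocity=velocity, persistence=min(persistence, 1.0))
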