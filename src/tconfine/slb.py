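"""Supported-lipid-bilayer characterization from single-molecule movies.

The workflow mirrors how functionalised bilayers are validated before a
cell experiment:

1. :func:`localize_spots` — detect diffraction-limited signals in every
   frame and refine them with an integrated-Gaussian fit (sub-pixel
   position, integrated brightness, size = Gaussian sigma in px).
2. :func:`filter_spots` — keep single-molecule-like sizes
   (0.75 px < size < 1.25 px) and find the first frame at which bleaching
   has thinned the field to the single-molecule density regime
   (≤ 0.09 μm⁻² by default).
3. :func:`single_molecule_brightness` — mean integrated brightness over a
   10-frame interval starting at that frame.
4. :func:`estimate_density` — ligand density of the untouched first
   frame: background-corrected mean brightness per μm² divided by the
   single-molecule brightness.
5. :func:`link_molecules` / :func:`molecule_diffusion` — trajectories
   (6 px search radius, no gap closing) and the diffusion constant from
   the ensemble MSD of all tracks with at least 5 steps.

Spot "size" throughout is the fitted Gaussian sigma in pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment, nnls
from skimage.feature import peak_local_max

from .io import ImageStack, px_to_um
from .motility import MSDCurve, _lag_sums, _track_positions

__all__ = [
    "DensityEstimate",
    "MoleculeMobility",
    "SLBError",
    "localize_spots",
    "filter_spots",
    "single_molecule_brightness",
    "estimate_density",
    "link_molecules",
    "molecule_diffusion",
]

LOC_COLUMNS = ["frame", "x_px", "y_px", "x_um", "y_um", "brightness", "size_px", "bg", "saturated"]


class SLBError(RuntimeError):
    """A bilayer-characterization step cannot produce a valid result."""


@dataclass
class DensityEstimate:
    """Ligand density of a bilayer by brightness normalization."""

    density: float               # μm⁻²
    brightness_per_um2: float    # background-corrected counts·μm⁻²
    single_molecule_brightness: float
    n_molecules: int             # localizations used for the brightness
    first_qualifying_frame: int


@dataclass
class MoleculeMobility:
    """Lateral mobility of bilayer-anchored molecules."""

    d: float                 # μm²/s
    mobile_fraction: float
    n_tracks: int
    msd: MSDCurve
    low_sample: bool = False


# ---------------------------------------------------------------------------
# localization


def _fit_gaussians_batched(
    frames: np.ndarray,
    frame_idx: np.ndarray,
    x0: np.ndarray,
    y0: np.ndarray,
    win: int = 4,
    n_iter: int = 12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Refine spot candidates with a symmetric integrated-Gaussian model.

    Fits ``I(x, y) = b + A·fx(x)·fy(y)`` per spot, where fx/fy are
    error-function pixel integrals of a Gaussian, by Gauss-Newton with
    analytic Jacobians, batched over all spots for throughput.  Returns
    refined (x, y), integrated brightness A, sigma, local background and
    a validity flag.
    """
    from scipy.special import erf

    n = len(x0)
    ny, nx = frames.shape[-2:]
    w = 2 * win + 1
    cx = np.clip(np.round(x0).astype(int), win, nx - win - 1)
    cy = np.clip(np.round(y0).astype(int), win, ny - win - 1)
    offs = np.arange(-win, win + 1)
    patches = frames[frame_idx[:, None, None], (cy[:, None] + offs)[:, :, None],
                     (cx[:, None] + offs)[:, None, :]].astype(float)

    # initial values from moments on a background-subtracted patch
    border = np.concatenate(
        [patches[:, 0, :], patches[:, -1, :], patches[:, 1:-1, 0], patches[:, 1:-1, -1]], axis=1
    )
    b = np.median(border, axis=1)
    resid0 = np.clip(patches - b[:, None, None], 0.0, None)
    tot = resid0.sum(axis=(1, 2)) + 1e-12
    mx = (resid0.sum(axis=1) * offs).sum(axis=1) / tot
    my = (resid0.sum(axis=2) * offs).sum(axis=1) / tot
    x = cx + mx
    y = cy + my
    a = tot.copy()
    sig = np.full(n, 1.0)

    xe = cx[:, None] + np.arange(-win, win + 2)[None, :] - 0.5  # pixel edges
    ye = cy[:, None] + np.arange(-win, win + 2)[None, :] - 0.5
    eye = np.eye(5)
    for _ in range(n_iter):
        s = sig * np.sqrt(2.0)
        ux = (xe - x[:, None]) / s[:, None]
        uy = (ye - y[:, None]) / s[:, None]
        fx = 0.5 * np.diff(erf(ux), axis=1)                      # (n, w)
        fy = 0.5 * np.diff(erf(uy), axis=1)
        gx = np.exp(-(ux**2))
        gy = np.exp(-(uy**2))
        inv_s2pi = 1.0 / (sig * np.sqrt(2.0 * np.pi))
        dfx_dx = -inv_s2pi[:, None] * np.diff(gx, axis=1)
        dfy_dy = -inv_s2pi[:, None] * np.diff(gy, axis=1)
        inv_spi = 1.0 / (sig * np.sqrt(np.pi))
        dfx_ds = -inv_spi[:, None] * np.diff(ux * gx, axis=1)
        dfy_ds = -inv_spi[:, None] * np.diff(uy * gy, axis=1)

        model = b[:, None, None] + a[:, None, None] * fy[:, :, None] * fx[:, None, :]
        r = model - patches                                       # (n, w, w)
        jac = np.empty((n, w, w, 5))
        jac[..., 0] = a[:, None, None] * fy[:, :, None] * dfx_dx[:, None, :]   # ∂/∂x
        jac[..., 1] = a[:, None, None] * dfy_dy[:, :, None] * fx[:, None, :]   # ∂/∂y
        jac[..., 2] = a[:, None, None] * (
            fy[:, :, None] * dfx_ds[:, None, :] + dfy_ds[:, :, None] * fx[:, None, :]
        )                                                                       # ∂/∂σ
        jac[..., 3] = fy[:, :, None] * fx[:, None, :]                           # ∂/∂A
        jac[..., 4] = 1.0                                                       # ∂/∂b
        j2 = jac.reshape(n, w * w, 5)
        jtj = np.einsum("npi,npj->nij", j2, j2) + 1e-9 * eye
        jtr = np.einsum("npi,np->ni", j2, r.reshape(n, w * w))
        try:
            delta = np.linalg.solve(jtj, jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.stack([np.linalg.lstsq(m, v, rcond=None)[0] for m, v in zip(jtj, jtr)])
        x -= np.clip(delta[:, 0], -1.0, 1.0)
        y -= np.clip(delta[:, 1], -1.0, 1.0)
        sig = np.clip(sig - np.clip(delta[:, 2], -0.25, 0.25), 0.2, float(win))
        a -= delta[:, 3]
        b -= delta[:, 4]
        a = np.clip(a, 1e-6, None)

    ok = (
        np.isfinite(x) & np.isfinite(y) & np.isfinite(a) & np.isfinite(sig)
        & (np.abs(x - cx) <= win) & (np.abs(y - cy) <= win)
    )
    return x, y, a, sig, b, ok


def localize_spots(stack: ImageStack, detection_threshold: float = 50.0) -> pd.DataFrame:
    """Localize diffraction-limited spots in every frame of a movie.

    Candidate local maxima of a lightly smoothed frame that rise more
    than ``detection_threshold`` counts above the frame background are
    refined by a 2D integrated-Gaussian fit.  Duplicates within 1 px are
    merged keeping the brighter.  Spots containing saturated pixels (at
    the dtype maximum, for integer data) are flagged and not fitted.
    """
    frames = np.asarray(stack.data, dtype=float)
    if frames.ndim != 3:
        raise ValueError("localize_spots expects a single-channel (frame, y, x) movie")
    saturation = None
    if np.issubdtype(stack.data.dtype, np.integer):
        saturation = np.iinfo(stack.data.dtype).max

    all_frames, all_x, all_y, sat_rows = [], [], [], []
    for t, frame in enumerate(frames):
        smooth = gaussian_filter(frame, 1.0)
        floor = np.percentile(smooth, 50)
        peaks = peak_local_max(
            smooth, min_distance=2, threshold_abs=floor + detection_threshold, exclude_border=2
        )
        for py, px_ in peaks:
            if saturation is not None and frame[
                max(py - 2, 0):py + 3, max(px_ - 2, 0):px_ + 3
            ].max() >= saturation:
                sat_rows.append((t, float(px_), float(py)))
                continue
            all_frames.append(t)
            all_x.append(float(px_))
            all_y.append(float(py))

    if not all_frames:
        df = pd.DataFrame(columns=LOC_COLUMNS)
    else:
        fi = np.asarray(all_frames)
        x, y, a, sig, b, ok = _fit_gaussians_batched(
            frames, fi, np.asarray(all_x), np.asarray(all_y)
        )
        df = pd.DataFrame(
            {
                "frame": fi[ok],
                "x_px": x[ok],
                "y_px": y[ok],
                "x_um": px_to_um(x[ok], stack.pixel_size),
                "y_um": px_to_um(y[ok], stack.pixel_size),
                "brightness": a[ok],
                "size_px": sig[ok],
                "bg": b[ok],
                "saturated": False,
            }
        )
        df = _merge_duplicates(df)
    if sat_rows:
        sat = pd.DataFrame(sat_rows, columns=["frame", "x_px", "y_px"])
        sat["x_um"] = px_to_um(sat["x_px"], stack.pixel_size)
        sat["y_um"] = px_to_um(sat["y_px"], stack.pixel_size)
        sat[["brightness", "size_px", "bg"]] = np.nan
        sat["saturated"] = True
        df = sat[LOC_COLUMNS] if df.empty else pd.concat([df, sat[LOC_COLUMNS]],
                                                         ignore_index=True)
    return df.sort_values(["frame", "x_px"], kind="stable").reset_index(drop=True)


def _merge_duplicates(df: pd.DataFrame, radius_px: float = 1.0) -> pd.DataFrame:
    """Merge localizations closer than ``radius_px`` within a frame, keeping the brighter."""
    keep = np.ones(len(df), dtype=bool)
    for _, idx in df.groupby("frame").indices.items():
        sub = df.iloc[idx]
        order = np.argsort(-sub["brightness"].to_numpy())
        xs = sub["x_px"].to_numpy()[order]
        ys = sub["y_px"].to_numpy()[order]
        taken_x, taken_y = [], []
        for j, (xj, yj) in enumerate(zip(xs, ys)):
            if any(np.hypot(xj - tx, yj - ty) < radius_px for tx, ty in zip(taken_x, taken_y)):
                keep[idx[order[j]]] = False
            else:
                taken_x.append(xj)
                taken_y.append(yj)
    return df[keep]


# ---------------------------------------------------------------------------
# filtering, brightness, density


def filter_spots(
    locs: pd.DataFrame,
    field_area: float,
    size_bounds: tuple[float, float] = (0.75, 1.25),
    density_threshold: float = 0.09,
    n_frames: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Size-filter localizations and find the single-molecule regime.

    Rows with fitted size outside the exclusive ``size_bounds`` (in px)
    are removed; the per-frame localization density (count / field area)
    is then compared against ``density_threshold`` and the first frame at
    or below it is returned.  Raises :class:`SLBError` when no frame
    qualifies or the table is empty.
    """
    if locs.empty:
        raise SLBError("no localizations: cannot determine a qualifying frame")
    lo, hi = size_bounds
    fitted = locs[~locs["saturated"].astype(bool)] if "saturated" in locs else locs
    filtered = fitted[(fitted["size_px"] > lo) & (fitted["size_px"] < hi)].copy()
    last = int(locs["frame"].max()) if n_frames is None else n_frames - 1
    counts = filtered.groupby("frame").size()
    density = counts.reindex(range(last + 1), fill_value=0) / field_area
    qualifying = density.index[density <= density_threshold]
    if len(qualifying) == 0:
        raise SLBError(
            f"density never below threshold {density_threshold} μm⁻² "
            f"(minimum {density.min():.3g} μm⁻²)"
        )
    return filtered.reset_index(drop=True), int(qualifying[0])


def single_molecule_brightness(
    locs: pd.DataFrame, first_qualifying_frame: int, interval: int = 10
) -> float:
    """Mean integrated brightness over the single-molecule interval.

    Averages rows with frame in ``[first_qualifying_frame,
    first_qualifying_frame + interval)``.
    """
    sel = locs[
        (locs["frame"] >= first_qualifying_frame)
        & (locs["frame"] < first_qualifying_frame + interval)
    ]
    if sel.empty:
        raise SLBError(
            f"no localizations in frames [{first_qualifying_frame}, "
            f"{first_qualifying_frame + interval})"
        )
    return float(sel["brightness"].mean())


def estimate_density(
    stack: ImageStack,
    smb: float,
    background: float | None = None,
    background_roi: np.ndarray | None = None,
    n_molecules: int = 0,
    first_qualifying_frame: int = 0,
) -> DensityEstimate:
    """Ligand density from the first movie frame by brightness normalization.

    The background-corrected mean brightness per μm² of the first frame
    is divided by the single-molecule brightness ``smb``.  Background is,
    in order of preference: the explicit value, the median of a
    user-designated molecule-free ROI mask, or the 1st percentile of the
    first frame.
    """
    if not smb > 0:
        raise SLBError(f"single-molecule brightness must be > 0, got {smb}")
    first = np.asarray(stack.data[0], dtype=float)
    if background is None:
        if background_roi is not None:
            background = float(np.median(first[background_roi]))
        else:
            background = float(np.percentile(first, 1))
    corrected = float(first.mean() - background)
    if corrected < 0:
        warnings.warn("background exceeds mean frame brightness; clipping to zero density")
        corrected = 0.0
    per_um2 = corrected / stack.pixel_size**2
    return DensityEstimate(
        density=per_um2 / smb,
        brightness_per_um2=per_um2,
        single_molecule_brightness=smb,
        n_molecules=n_molecules,
        first_qualifying_frame=first_qualifying_frame,
    )


# ---------------------------------------------------------------------------
# tracking and diffusion


def link_molecules(
    locs: pd.DataFrame, search_radius: float = 6.0, pixel_size: float | None = None
) -> pd.DataFrame:
    """Link localizations into trajectories, frame to frame.

    Assignment between consecutive frames minimizes total squared
    displacement (Hungarian algorithm) among candidate pairs closer than
    ``search_radius`` pixels; unmatched localizations start new tracks.
    No gap closing.  Returns a table with columns ``particle``, ``frame``,
    ``x_um``, ``y_um`` (``x_px``/``y_px`` retained).
    """
    if locs.empty:
        return pd.DataFrame(columns=["particle", "frame", "x_px", "y_px", "x_um", "y_um"])
    locs = locs[~locs.get("saturated", False).astype(bool)].sort_values("frame")
    frames = sorted(locs["frame"].unique())
    big = 1e12
    particle = np.full(len(locs), -1, dtype=int)
    locs = locs.reset_index(drop=True)
    next_id = 0
    prev_idx: np.ndarray | None = None
    prev_frame = None
    for f in frames:
        cur_idx = np.flatnonzero(locs["frame"].to_numpy() == f)
        if prev_idx is not None and prev_frame == f - 1 and len(prev_idx) and len(cur_idx):
            pa = locs.loc[prev_idx, ["x_px", "y_px"]].to_numpy()
            cb = locs.loc[cur_idx, ["x_px", "y_px"]].to_numpy()
            d = np.linalg.norm(pa[:, None, :] - cb[None, :, :], axis=2)
            cost = np.where(d <= search_radius, d**2, big)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if d[r, c] <= search_radius:
                    particle[cur_idx[c]] = particle[prev_idx[r]]
        for i in cur_idx:
            if particle[i] < 0:
                particle[i] = next_id
                next_id += 1
        prev_idx, prev_frame = cur_idx, f
    out = locs.copy()
    out["particle"] = particle
    cols = ["particle", "frame", "x_px", "y_px", "x_um", "y_um"]
    return out[cols].sort_values(["particle", "frame"]).reset_index(drop=True)


def molecule_diffusion(
    tracks: pd.DataFrame,
    frame_interval: float,
    min_steps: int = 5,
    n_fit_lags: int = 5,
    immobile_cutoff: float = 0.01,
) -> MoleculeMobility:
    """Diffusion constant and mobile fraction from linked trajectories.

    Only tracks with at least ``min_steps`` steps are retained.  D comes
    from a weighted linear fit of the ensemble MSD over the first
    ``n_fit_lags`` lags, MSD(t) = 4Dt + c with c ≥ 0 absorbing the
    localization error (the zero-lag point is never used).  The mobile
    fraction is the fraction of retained tracks whose individual D
    exceeds ``immobile_cutoff`` (μm²/s).
    """
    sizes = tracks.groupby("particle").size()
    keep_ids = sizes.index[sizes - 1 >= min_steps]
    kept = tracks[tracks["particle"].isin(keep_ids)]
    if kept.empty:
        raise SLBError(f"no track has at least {min_steps} steps")
    curve = pooled_msd_short(kept, frame_interval, n_fit_lags)
    t = curve.lag_s
    w = np.sqrt(curve.n_pairs.astype(float))
    design = np.column_stack([4.0 * t, np.ones_like(t)])
    theta, _ = nnls(design * w[:, None], curve.msd * w)
    d = float(theta[0])

    positions = _track_positions(kept)
    n_tracks = len(positions)
    mobile = 0
    for pos in positions:
        lags = min(4, len(pos) - 1)
        s, c = _lag_sums([pos], lags)
        msd_i = s[0] / c[0]
        ti = np.arange(1, lags + 1) * frame_interval
        if lags >= 2:
            slope = np.polyfit(ti, msd_i, 1)[0]
        else:
            slope = msd_i[0] / ti[0]
        if max(slope, 0.0) / 4.0 > immobile_cutoff:
            mobile += 1
    low = n_tracks < 10
    if low:
        warnings.warn(f"only {n_tracks} tracks retained; diffusion estimate is low-sample")
    return MoleculeMobility(
        d=d, mobile_fraction=mobile / n_tracks, n_tracks=n_tracks, msd=curve, low_sample=low
    )


def pooled_msd_short(tracks: pd.DataFrame, frame_interval: float, max_lag: int) -> MSDCurve:
    """Ensemble MSD restricted to the first ``max_lag`` lags."""
    from .motility import pooled_msd

    return pooled_msd(tracks, frame_interval, max_lag)
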