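"""Fura-2 ratiometric calcium imaging of confined T cells.

A Fura-2 recording consists of two interleaved excitation channels
(340 nm and 380 nm).  The *sum* stack (I340 + I380) carries the cell
morphology and drives segmentation and tracking; the *ratio* stack,
(I340 − B340)/(I380 − B380), reports intracellular calcium: the ratio
rises when [Ca²⁺] rises.  Per tracked cell we report the sectional cell
area (segmented 2D footprint, μm²) and the Ca²⁺ ratio (mean pixel ratio
over the segmented footprint).

Confinement experiments consist of two recordings of the same field —
before and after the actuator is applied — which are joined per cell by
centroid proximity; window statistics then compare each cell's mean area
and ratio between a pre-confinement and a post-confinement time window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "RatioStacks",
    "make_sum_ratio",
    "segment_cells",
    "track_cells",
    "join_recordings",
    "window_means",
]

SERIES_COLUMNS = ["cell", "frame", "x_um", "y_um", "area_um2", "ratio", "on_border"]


@dataclass
class RatioStacks:
    """Sum and background-corrected ratio stacks of a Fura-2 recording."""

    sum: np.ndarray     # I340 + I380
    ratio: np.ndarray   # (I340 − B340)/(I380 − B380) where valid, else NaN
    valid: np.ndarray   # denominator > 0


def make_sum_ratio(
    stack340: np.ndarray, stack380: np.ndarray, b340: float, b380: float
) -> RatioStacks:
    """Build the Fura-2 sum and ratio stacks from the two emission stacks.

    Pixels whose background-corrected 380 nm intensity is not positive
    are masked invalid (ratio NaN), never infinite.
    """
    i340 = np.asarray(stack340, dtype=float)
    i380 = np.asarray(stack380, dtype=float)
    if i340.shape != i380.shape:
        raise ValueError(f"channel shapes differ: {i340.shape} vs {i380.shape}")
    denom = i380 - b380
    valid = denom > 0
    ratio = np.full_like(i340, np.nan)
    np.divide(i340 - b340, denom, out=ratio, where=valid)
    return RatioStacks(sum=i340 + i380, ratio=ratio, valid=valid)


def segment_cells(
    frame: np.ndarray,
    pixel_size: float,
    smooth_sigma: float = 1.0,
    min_area_um2: float = 20.0,
) -> np.ndarray:
    """Segment cells in one (sum-stack) frame.

    Recipe: Gaussian smoothing → global Otsu threshold → hole filling →
    watershed split on distance-transform maxima → discard objects below
    ``min_area_um2``.  Returns a label mask with consecutive positive
    integer labels; an empty or flat frame yields an all-zero mask.
    """
    img = np.asarray(frame, dtype=float)
    if np.ptp(img) <= 1e-12:
        return np.zeros(img.shape, dtype=np.int32)
    smooth = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    mask = smooth > threshold_otsu(smooth)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    mask = ndimage.binary_fill_holes(mask)

    dist = ndimage.distance_transform_edt(mask)
    min_sep = max(3, int(round(np.sqrt(min_area_um2 / np.pi) / pixel_size)))
    peaks = peak_local_max(dist, min_distance=min_sep, labels=mask, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=mask)

    min_px = min_area_um2 / pixel_size**2
    out = np.zeros(img.shape, dtype=np.int32)
    next_label = 1
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        if region.sum() >= min_px:
            out[region] = next_label
            next_label += 1
    return out


def _frame_records(
    labels: np.ndarray, ratio_frame: np.ndarray | None, pixel_size: float, frame: int
) -> list[dict]:
    ny, nx = labels.shape
    rows = []
    for prop in regionprops(labels):
        cy, cx = prop.centroid
        minr, minc, maxr, maxc = prop.bbox
        on_border = minr == 0 or minc == 0 or maxr == ny or maxc == nx
        if ratio_frame is not None:
            vals = ratio_frame[labels == prop.label]
            ratio = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
        else:
            ratio = np.nan
        rows.append(
            {
                "cell": prop.label,
                "frame": frame,
                "x_um": (cx + 0.5) * pixel_size,
                "y_um": (cy + 0.5) * pixel_size,
                "area_um2": prop.area * pixel_size**2,
                "ratio": ratio,
                "on_border": on_border,
            }
        )
    return rows


def track_cells(
    masks: list[np.ndarray] | np.ndarray,
    ratio: RatioStacks | None,
    pixel_size: float,
    max_displacement_um: float = 15.0,
) -> pd.DataFrame:
    """Link per-frame segmentations into per-cell time series.

    Frame-to-frame identity is resolved by greedy nearest-centroid
    matching with a maximum displacement (no gap closing); unmatched
    cells end or start tracks.  Per cell and frame the sectional area
    (label pixel count × pixel_size²) and the Ca²⁺ ratio (mean of the
    ratio stack over valid labeled pixels) are emitted, along with a flag
    for cells touching the image border (whose area is censored).
    """
    records: list[dict] = []
    prev: list[dict] = []
    next_id = 0
    for t, labels in enumerate(masks):
        ratio_frame = ratio.ratio[t] if ratio is not None else None
        current = _frame_records(labels, ratio_frame, pixel_size, t)
        assigned = [-1] * len(current)
        if prev and current:
            pairs = sorted(
                (
                    (np.hypot(c["x_um"] - p["x_um"], c["y_um"] - p["y_um"]), i, j)
                    for i, p in enumerate(prev)
                    for j, c in enumerate(current)
                ),
                key=lambda triple: triple[0],
            )
            used_p: set[int] = set()
            for dist, i, j in pairs:
                if dist > max_displacement_um:
                    break
                if i in used_p or assigned[j] >= 0:
                    continue
                assigned[j] = prev[i]["cell"]
                used_p.add(i)
        for j, c in enumerate(current):
            if assigned[j] < 0:
                assigned[j] = next_id
                next_id += 1
            c["cell"] = assigned[j]
        records.extend(current)
        prev = current
    if not records:
        return pd.DataFrame(columns=SERIES_COLUMNS)
    df = pd.DataFrame(records, columns=SERIES_COLUMNS)
    return df.sort_values(["cell", "frame"]).reset_index(drop=True)


def join_recordings(
    pre: pd.DataFrame, post: pd.DataFrame, limit_um: float = 25.0
) -> tuple[pd.DataFrame, int]:
    """Join pre- and post-confinement recordings of the same field.

    Cells are matched across the acquisition gap by centroid proximity
    (last pre position vs first post position), nearest pairs first;
    distance ties break toward the lower pre cell id.  Matched post
    tracks inherit the pre cell id; unmatched cells are retained with a
    single-recording label.  Post frames are renumbered to continue after
    the pre recording; the returned join index is the first post frame.
    """
    join_index = int(pre["frame"].max()) + 1 if len(pre) else 0
    pre = pre.copy()
    pre["recording"] = "pre"
    if not len(post):
        return pre, join_index

    last_pre = pre.loc[pre.groupby("cell")["frame"].idxmax()]
    first_post = post.loc[post.groupby("cell")["frame"].idxmin()]
    pairs = []
    for _, p in last_pre.iterrows():
        for _, q in first_post.iterrows():
            dist = np.hypot(p["x_um"] - q["x_um"], p["y_um"] - q["y_um"])
            if dist <= limit_um:
                pairs.append((dist, int(p["cell"]), int(q["cell"])))
    pairs.sort(key=lambda t: (t[0], t[1]))
    mapping: dict[int, int] = {}
    used_pre: set[int] = set()
    for _, pid, qid in pairs:
        if pid in used_pre or qid in mapping:
            continue
        mapping[qid] = pid
        used_pre.add(pid)

    post = post.copy()
    post["recording"] = "post"
    post["frame"] = post["frame"] + join_index
    fresh = int(pre["cell"].max()) + 1 if len(pre) else 0
    new_ids = {}
    for qid in post["cell"].unique():
        if qid in mapping:
            new_ids[qid] = mapping[qid]
        else:
            new_ids[qid] = fresh
            fresh += 1
    post["cell"] = post["cell"].map(new_ids)
    joined = pd.concat([pre, post], ignore_index=True)
    joined = joined.sort_values(["cell", "frame"]).reset_index(drop=True)
    matched_ids = set(mapping.values())
    joined["matched"] = joined["cell"].isin(matched_ids)
    return joined, join_index


def window_means(
    series: pd.DataFrame,
    pre_window: tuple[int, int],
    post_window: tuple[int, int],
) -> pd.DataFrame:
    """Per-cell mean area and ratio in a pre and a post window.

    Windows are half-open frame intervals ``[start, end)`` and must not
    overlap; the pre window must end at or before the post window starts.
    Cells absent from either window are excluded (their count is recorded
    in ``df.attrs['n_excluded']``).
    """
    (a0, a1), (b0, b1) = pre_window, post_window
    if a1 > b0:
        raise ValueError("pre and post windows must not overlap")
    pre = series[(series["frame"] >= a0) & (series["frame"] < a1)]
    post = series[(series["frame"] >= b0) & (series["frame"] < b1)]
    if pre.empty or post.empty:
        raise ValueError("empty time window")
    agg = {"area_um2": "mean", "ratio": "mean"}
    pre_m = pre.groupby("cell").agg(agg)
    post_m = post.groupby("cell").agg(agg)
    common = pre_m.index.intersection(post_m.index)
    n_excluded = len(pre_m.index.union(post_m.index)) - len(common)
    out = pd.DataFrame(
        {
            "cell": common,
            "area_pre": pre_m.loc[common, "area_um2"].to_numpy(),
            "area_post": post_m.loc[common, "area_um2"].to_numpy(),
            "ratio_pre": pre_m.loc[common, "ratio"].to_numpy(),
            "ratio_post": post_m.loc[common, "ratio"].to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["pre_window"] = pre_window
    out.attrs["post_window"] = post_window
    return out
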