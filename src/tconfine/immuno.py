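"""Quantification of two-channel immunostained confocal images.

For fixed T cells stained with DAPI (nuclei) and an anti-pErk1/2
antibody (cytoplasmic signal of TCR-downstream MAPK activation), this
module segments both channels independently, measures sectional nucleus
and cell areas in μm², and reports the mean pErk1/2 intensity within
each pErk-segmented cell.  Nuclei are paired with cells by containment
of the nucleus centroid; unpaired objects are retained and flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .fura import segment_cells

__all__ = ["segment_channel", "measure_perk"]


def segment_channel(
    image: np.ndarray, pixel_size: float, min_area_um2: float = 20.0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment one channel and tabulate per-label sectional areas.

    Uses the same smoothing → Otsu → watershed recipe as the Fura-2 cell
    segmentation.  Returns the label mask and a table with columns
    ``label`` and ``area_um2``.
    """
    labels = segment_cells(image, pixel_size, min_area_um2=min_area_um2)
    rows = [
        {"label": p.label, "area_um2": p.area * pixel_size**2, "x_um": (p.centroid[1] + 0.5) * pixel_size,
         "y_um": (p.centroid[0] + 0.5) * pixel_size}
        for p in regionprops(labels)
    ]
    return labels, pd.DataFrame(rows, columns=["label", "area_um2", "x_um", "y_um"])


def measure_perk(
    perk_image: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray | None = None,
    pixel_size: float = 1.0,
) -> pd.DataFrame:
    """Per-cell pErk1/2 mean intensity, with optional nucleus pairing.

    The mean intensity is measured within each labeled region of the
    pErk-channel segmentation (``cell_mask``).  If a nucleus label mask
    is given, each nucleus is paired with the cell containing its
    centroid; nuclei outside every cell appear as rows with a nucleus
    area but no cell (``cell_id`` NaN, flagged ``unpaired``).
    """
    perk = np.asarray(perk_image, dtype=float)
    if perk.shape != cell_mask.shape:
        raise ValueError("perk image and cell mask shapes differ")
    records = {}
    for prop in regionprops(cell_mask, intensity_image=perk):
        records[prop.label] = {
            "cell_id": prop.label,
            "cell_area_um2": prop.area * pixel_size**2,
            "perk_mean": float(prop.intensity_mean),
            "nucleus_area_um2": np.nan,
            "unpaired": False,
        }
    unpaired = []
    if nucleus_mask is not None:
        for prop in regionprops(nucleus_mask):
            cy, cx = prop.centroid
            area = prop.area * pixel_size**2
            owner = int(cell_mask[int(round(cy)), int(round(cx))])
            if owner > 0 and owner in records:
                records[owner]["nucleus_area_um2"] = area
            else:
                unpaired.append(
                    {"cell_id": np.nan, "cell_area_um2": np.nan, "perk_mean": np.nan,
                     "nucleus_area_um2": area, "unpaired": True}
                )
    cols = ["cell_id", "cell_area_um2", "perk_mean", "nucleus_area_um2", "unpaired"]
    return pd.DataFrame(list(records.values()) + unpaired, columns=cols)
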