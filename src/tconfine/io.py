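"""Image stacks, tables and run configuration.

All pipeline stages exchange two kinds of objects: :class:`ImageStack`
(pixel data plus mandatory physical calibration) and plain pandas
DataFrames serialised as tab-separated text.  Stacks are stored as
multi-page TIFF, one file per channel, with a plain-text sidecar that
carries the calibration; reading a stack without calibration is a hard
error, never a silent assumption.

Coordinate convention: pixel indices are 0-based with the origin at the
top-left corner, x = column, y = row.  Physical coordinates refer to
pixel centres, ``x_um = (col + 0.5) * pixel_size``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageStack",
    "CalibrationError",
    "FormatError",
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
    "RunConfig",
    "px_to_um",
    "um_to_px",
]


class CalibrationError(ValueError):
    """Physical calibration metadata is missing or invalid."""


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


def px_to_um(index: np.ndarray | float, pixel_size: float) -> np.ndarray | float:
    """Convert 0-based pixel indices to physical pixel-centre coordinates."""
    return (np.asarray(index, dtype=float) + 0.5) * pixel_size


def um_to_px(coord: np.ndarray | float, pixel_size: float) -> np.ndarray | float:
    """Inverse of :func:`px_to_um` (returns fractional pixel indices)."""
    return np.asarray(coord, dtype=float) / pixel_size - 0.5


@dataclass
class ImageStack:
    """N-dimensional pixel data with physical calibration.

    Parameters
    ----------
    data
        Pixel counts, indexed ``(frame|z, y, x)`` for a single channel or
        ``(channel, frame, y, x)`` for multi-channel time series.
    pixel_size
        Lateral calibration in μm per pixel (mandatory, > 0).
    frame_interval
        Seconds between frames for time series.
    z_step
        μm between slices for axial stacks.
    channels
        Channel labels, one per leading channel axis entry (optional).
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float | None = None
    z_step: float | None = None
    channels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not (self.pixel_size > 0):
            raise CalibrationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_interval is not None and not (self.frame_interval > 0):
            raise CalibrationError("frame_interval must be > 0")
        if self.z_step is not None and not (self.z_step > 0):
            raise CalibrationError("z_step must be > 0")
        if self.channels is not None:
            if self.data.ndim < 3 or len(self.channels) != self.data.shape[0]:
                raise ValueError(
                    f"{len(self.channels)} channel labels for data shape {self.data.shape}"
                )

    @property
    def n_channels(self) -> int:
        return 1 if self.channels is None else len(self.channels)

    @property
    def n_frames(self) -> int:
        return self.data.shape[1] if self.channels is not None else self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    @property
    def field_area(self) -> float:
        """Field-of-view area in μm²."""
        ny, nx = self.frame_shape
        return ny * nx * self.pixel_size**2

    def channel(self, label: str) -> "ImageStack":
        """Extract a single channel as a new stack."""
        if self.channels is None:
            raise ValueError("stack has no channel axis")
        idx = self.channels.index(label)
        return replace(self, data=self.data[idx], channels=None)


_META_KEYS = ("pixel_size_um", "frame_interval_s", "z_step_um", "channels")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.txt")


def write_stack(stack: ImageStack, path: str | os.PathLike) -> list[Path]:
    """Write a stack as multi-page TIFF plus a plain-text metadata sidecar.

    Multi-channel stacks are written one file per channel with the channel
    label appended to the stem.  Returns the list of TIFF paths written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if stack.channels is not None:
        paths = []
        for i, label in enumerate(stack.channels):
            p = path.with_name(f"{path.stem}_{label}{path.suffix}")
            tifffile.imwrite(p, stack.data[i], photometric="minisblack")
            paths.append(p)
    else:
        tifffile.imwrite(path, stack.data, photometric="minisblack")
        paths = [path]
    lines = [f"pixel_size_um = {stack.pixel_size!r}"]
    if stack.frame_interval is not None:
        lines.append(f"frame_interval_s = {stack.frame_interval!r}")
    if stack.z_step is not None:
        lines.append(f"z_step_um = {stack.z_step!r}")
    if stack.channels is not None:
        lines.append("channels = " + ",".join(stack.channels))
    _sidecar_path(path).write_text("\n".join(lines) + "\n")
    return paths


def _read_sidecar(path: Path) -> dict:
    meta = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"malformed sidecar line: {line!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _META_KEYS:
            raise FormatError(f"unknown sidecar key {key!r}")
        meta[key] = value.strip()
    return meta


def read_stack(
    path: str | os.PathLike,
    *,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    z_step: float | None = None,
) -> ImageStack:
    """Read a single-channel multi-page TIFF stack.

    Calibration comes from the sidecar written by :func:`write_stack`, or
    from explicit keyword overrides.  Raises :class:`CalibrationError` if
    no pixel size can be established.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent page shapes in {path.name}: {sorted(shapes)}")
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]

    sidecar = _sidecar_path(path)
    # channel files share the base sidecar ("stack_340.tif" -> "stack.tif.meta.txt")
    if not sidecar.exists() and "_" in path.stem:
        base = path.with_name(path.stem.rsplit("_", 1)[0] + path.suffix)
        alt = _sidecar_path(base)
        if alt.exists():
            sidecar = alt
    meta = _read_sidecar(sidecar) if sidecar.exists() else {}

    ps = pixel_size if pixel_size is not None else _maybe_float(meta.get("pixel_size_um"))
    if ps is None:
        raise CalibrationError(
            f"no pixel size for {path.name}: sidecar absent and no override given"
        )
    fi = frame_interval if frame_interval is not None else _maybe_float(meta.get("frame_interval_s"))
    zs = z_step if z_step is not None else _maybe_float(meta.get("z_step_um"))
    return ImageStack(data, pixel_size=ps, frame_interval=fi, z_step=zs)


def _maybe_float(value: str | None) -> float | None:
    return None if value is None else float(value)


def write_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a DataFrame as tab-separated text with a header row.

    Floats are written with 12 significant digits so that a round trip
    through :func:`read_table` is lossless at that precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tab-separated table written by :func:`write_table`.

    Columns that are predominantly numeric must parse completely; a stray
    non-numeric cell raises :class:`FormatError` naming its row and column.
    Fully non-numeric columns are kept as strings.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicated header names in {path.name}: {dupes}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for col in df.columns:
        series = df[col]
        converted = pd.to_numeric(series.replace("", np.nan), errors="coerce")
        blank = series.str.strip() == ""
        bad = converted.isna() & ~blank
        if bad.any():
            if bad.all():  # label-like column
                out[col] = series
                continue
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-numeric value {series.iloc[row]!r} in numeric column "
                f"{col!r}, row {row} of {path.name}"
            )
        out[col] = converted
    return pd.DataFrame(out, columns=df.columns)


# ---------------------------------------------------------------------------
# Run configuration

#: Stage-parameter defaults.  Values tagged in comments follow the printed
#: acquisition/analysis parameters of the study this toolkit reproduces.
DEFAULTS: dict[str, dict] = {
    "slb": {
        "detection_threshold": 100.0,   # counts above local background
        "size_min_px": 0.75,            # exclusive lower size bound
        "size_max_px": 1.25,            # exclusive upper size bound
        "density_threshold": 0.09,      # μm⁻², single-molecule regime
        "brightness_interval_frames": 10,
        "search_radius_px": 6.0,        # linking radius
        "min_steps": 5,                 # trajectory length filter
        "immobile_cutoff": 0.01,        # μm²/s, mobile-fraction criterion
        "n_fit_lags": 5,
    },
    "fura": {
        "smooth_sigma_px": 1.0,
        "min_area_um2": 20.0,
        "max_displacement_um": 15.0,
        "join_limit_um": 25.0,
    },
    "motility": {
        "n_boot": 1000,
        "max_lag_fraction": 0.25,       # of the median track length
        "velocity_window": 3,
    },
    "immuno": {
        "min_area_um2": 20.0,
        "min_nucleus_area_um2": 5.0,
    },
    "mech": {
        "poly_order": 12,
        "controller_step_mbar": 0.1,
    },
    "stats": {
        "alpha": 0.05,
        "notch_constant": 1.57,
    },
    "simulate": {
        "seed": 0,
    },
}


@dataclass
class RunConfig:
    """Flat, human-editable stage configuration.

    Sections are keyed by pipeline stage; every threshold carries the
    published default.  Unknown sections or keys are rejected so that a
    typo never silently falls back to a default.
    """

    params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {k: dict(v) for k, v in DEFAULTS.items()}
        for section, values in self.params.items():
            if section not in merged:
                raise KeyError(f"unknown config section {section!r}")
            if not isinstance(values, dict):
                raise TypeError(f"config section {section!r} must be a mapping")
            for key, val in values.items():
                if key not in merged[section]:
                    raise KeyError(f"unknown config key {section}.{key}")
                merged[section][key] = val
        self.params = merged

    def __getitem__(self, section: str) -> dict:
        return self.params[section]

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.params, fh, sort_keys=True)
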