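"""Confinement geometry and actuator-membrane mechanics.

Two groups of measurements live here.

*Confinement validation.*  A membrane-stained cell squeezed between two
glass surfaces shows two bright lamellae in an axial (z) stack — the top
and bottom plasma membranes.  :func:`cell_height_from_zstack` measures
the distance between the two outermost intensity maxima of the axial
profile through the cell centre, with parabolic sub-sample peak
interpolation, and compares it against the preset spacer-bead diameter.

*Membrane mechanics.*  Deflection profiles of the pressure-driven
elastomer membrane are fitted with even polynomials up to order 12
(symmetry about the apex).  From the fitted profile the arc length gives
the engineering strain ε = (L − 2a)/(2a) of the radial section of
half-width a; the apex-height-vs-pressure relation is close to linear,
and its slope times the pressure-controller step (0.1 mbar) is the
theoretical gap-height resolution of the device.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.signal import find_peaks
from scipy.stats import linregress

from .io import ImageStack
from .simulate import DeflectionProfile

__all__ = [
    "HeightEstimate",
    "ProfileFit",
    "PressureFit",
    "GapReport",
    "cell_height_from_zstack",
    "fit_profile",
    "arc_strain",
    "pressure_linearity",
    "expected_gap",
]


class UnresolvableHeightError(RuntimeError):
    """The axial profile does not resolve two membrane lamellae."""


@dataclass
class HeightEstimate:
    """Confinement height of a cell from an axial intensity profile."""

    height: float          # μm
    method: str            # "peak-to-peak" or "fwhm"
    z_step: float          # μm
    uncertainty: float     # μm, at least z_step/2


@dataclass
class ProfileFit:
    """Even-polynomial fit of a membrane deflection profile.

    The polynomial is expressed in the normalised coordinate
    u = x / x_scale: z(x) = Σₖ coeffs[k] · u^(2k).  ``apex`` is z(0).
    """

    coeffs: np.ndarray     # even-power coefficients, ascending
    x_scale: float
    order: int
    apex: float
    pressure: float | None = None

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        u2 = (np.asarray(x, dtype=float) / self.x_scale) ** 2
        return sum(c * u2**k for k, c in enumerate(self.coeffs))

    def derivative(self, x: np.ndarray | float) -> np.ndarray | float:
        """dz/dx in z-units per x-unit."""
        x = np.asarray(x, dtype=float)
        u = x / self.x_scale
        out = np.zeros_like(u)
        for k, c in enumerate(self.coeffs):
            if k > 0:
                out = out + c * 2 * k * u ** (2 * k - 1)
        return out / self.x_scale

    @property
    def coeffs_x(self) -> np.ndarray:
        """Coefficients of the even powers of physical x (x⁰, x², …)."""
        return self.coeffs / self.x_scale ** (2 * np.arange(len(self.coeffs)))


@dataclass
class PressureFit:
    """Linear apex-deflection vs pressure relation."""

    slope: float           # μm/mbar
    intercept: float       # μm
    r_squared: float
    resolution: float      # μm per controller step
    controller_step: float # mbar


@dataclass
class GapReport:
    """Expected gap between the levelled confinement surface and the glass."""

    gap_map: np.ndarray
    min_gap: float
    max_gap: float
    mean_gap: float
    coplanarity: float     # max − min gap within the footprint


# ---------------------------------------------------------------------------
# confinement height


def _refine_peak(z: np.ndarray, profile: np.ndarray, idx: int) -> float:
    """Sub-sample peak position by 3-point parabolic interpolation.

    Interpolation is done on log-intensity when the three samples are
    positive (exact for Gaussian-shaped lamellae), otherwise on the raw
    values.
    """
    if idx == 0 or idx == len(profile) - 1:
        return float(z[idx])
    y = profile[idx - 1:idx + 2]
    if np.all(y > 0):
        y = np.log(y)
    denom = y[0] - 2 * y[1] + y[2]
    if denom >= 0:
        return float(z[idx])
    delta = 0.5 * (y[0] - y[2]) / denom
    return float(z[idx] + np.clip(delta, -0.5, 0.5) * (z[1] - z[0]))


def cell_height_from_zstack(stack: ImageStack) -> HeightEstimate:
    """Cell height = axial distance between the two outermost membrane peaks.

    The axial profile is taken through the lateral intensity centroid of
    the stack.  When the two lamellae merge into a single peak, the full
    width at half maximum of the envelope is reported instead; if even
    that is below 2 z-steps the height is unresolvable.
    """
    if stack.z_step is None:
        raise ValueError("stack has no z calibration")
    data = np.asarray(stack.data, dtype=float)
    proj = data.sum(axis=0)
    total = proj.sum()
    if total <= 0:
        raise UnresolvableHeightError("empty stack")
    ny, nx = proj.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy = int(round((proj * yy).sum() / total))
    cx = int(round((proj * xx).sum() / total))
    lo_y, hi_y = max(cy - 1, 0), min(cy + 2, ny)
    lo_x, hi_x = max(cx - 1, 0), min(cx + 2, nx)
    profile = data[:, lo_y:hi_y, lo_x:hi_x].mean(axis=(1, 2))
    z = np.arange(len(profile)) * stack.z_step

    peaks, _ = find_peaks(profile, prominence=0.05 * profile.max())
    if len(peaks) >= 2:
        z_lo = _refine_peak(z, profile, peaks[0])
        z_hi = _refine_peak(z, profile, peaks[-1])
        height = z_hi - z_lo
        if height >= 2 * stack.z_step:
            return HeightEstimate(
                height=height, method="peak-to-peak", z_step=stack.z_step,
                uncertainty=stack.z_step / 2,
            )
    # lamellae merged: fall back to the envelope FWHM
    half = profile.max() / 2.0
    above = profile >= half
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise UnresolvableHeightError("no signal above half maximum")
    fwhm = (idx[-1] - idx[0]) * stack.z_step
    if fwhm < 2 * stack.z_step:
        raise UnresolvableHeightError(
            f"single peak with FWHM {fwhm:.2f} μm < 2 z-steps: height unresolvable"
        )
    return HeightEstimate(
        height=float(fwhm), method="fwhm", z_step=stack.z_step, uncertainty=stack.z_step / 2
    )


# ---------------------------------------------------------------------------
# membrane mechanics


def fit_profile(
    profile: DeflectionProfile | tuple[np.ndarray, np.ndarray], order: int = 12
) -> ProfileFit:
    """Least-squares even-polynomial fit of a deflection profile.

    Only even powers of x enter (the membrane is symmetric about its
    apex); the default order is 12.  A rank-deficient design triggers an
    automatic order reduction with a warning.
    """
    if isinstance(profile, DeflectionProfile):
        x, zv, pressure = profile.x_mm, profile.z_um, profile.pressure_mbar
    else:
        x, zv = np.asarray(profile[0], float), np.asarray(profile[1], float)
        pressure = None
    if order % 2 or order < 2:
        raise ValueError("order must be a positive even integer")
    if len(x) < order // 2 + 1:
        raise ValueError(f"need at least {order // 2 + 1} samples for order {order}")
    scale = float(np.max(np.abs(x))) or 1.0
    u2 = (x / scale) ** 2
    while order >= 2:
        design = np.column_stack([u2**k for k in range(order // 2 + 1)])
        coeffs, _, rank, _ = np.linalg.lstsq(design, zv, rcond=None)
        if rank == design.shape[1]:
            break
        warnings.warn(f"rank-deficient design at order {order}; reducing")
        order -= 2
    return ProfileFit(coeffs=coeffs, x_scale=scale, order=order,
                      apex=float(coeffs[0]), pressure=pressure)


def arc_strain(fit: ProfileFit, half_width: float, z_to_x_units: float = 1e-3) -> float:
    """Engineering strain of the membrane section from the fitted profile.

    The arc length L = ∫√(1 + z′(x)²) dx over [−a, a] is evaluated by
    adaptive quadrature (relative tolerance 1e-9); the strain is
    ε = (L − 2a)/(2a), referenced to the flat chord.  ``z_to_x_units``
    converts the profile's z unit into the x unit (default μm → mm).
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")

    def integrand(x: float) -> float:
        slope = fit.derivative(x) * z_to_x_units
        return float(np.sqrt(1.0 + slope * slope))

    length, _ = quad(integrand, -half_width, half_width, epsabs=1e-12, epsrel=1e-10, limit=200)
    return (length - 2 * half_width) / (2 * half_width)


def pressure_linearity(
    pressures: np.ndarray, apex_heights: np.ndarray, controller_step: float = 0.1
) -> PressureFit:
    """Ordinary least-squares line through (pressure, apex deflection).

    The gap-height resolution is the slope times the pressure-controller
    step (default 0.1 mbar).
    """
    p = np.asarray(pressures, dtype=float)
    h = np.asarray(apex_heights, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two pressures")
    res = linregress(p, h)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return PressureFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        resolution=float(res.slope) * controller_step,
        controller_step=controller_step,
    )


def expected_gap(
    topography: np.ndarray,
    reference_mask: np.ndarray,
    footprint_mask: np.ndarray,
    reference_offset: float,
) -> GapReport:
    """Expected gap map between the confining disc and the cover glass.

    The topography is levelled so the designated reference region has
    zero mean height; within the disc footprint the gap is the reference
    plane offset minus the levelled height.  Coplanarity is the max−min
    gap across the footprint (0 for a perfectly parallel disc).
    """
    topo = np.asarray(topography, dtype=float)
    ref = np.asarray(reference_mask, dtype=bool)
    foot = np.asarray(footprint_mask, dtype=bool)
    if not ref.any():
        raise ValueError("reference region is empty")
    if not foot.any():
        raise ValueError("footprint region is empty")
    levelled = topo - topo[ref].mean()
    gap_map = np.where(foot, reference_offset - levelled, np.nan)
    vals = gap_map[foot]
    return GapReport(
        gap_map=gap_map,
        min_gap=float(vals.min()),
        max_gap=float(vals.max()),
        mean_gap=float(vals.mean()),
        coplanarity=float(vals.max() - vals.min()),
    )
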