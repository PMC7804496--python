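"""Viewing geometry and retinal sampling.

Converts between the three coordinate systems a psychophysics display
involves: screen pixels, degrees of visual angle, and retinal millimetres.
Also maps eccentricity to the scale of midget ganglion cell receptive
fields, which sets the centre (foreground) Gaussian of the
difference-of-Gaussians contrast kernel.

Two ways to obtain the foreground sigma coexist:

* *reproduction mode* — an explicitly tabulated sigma in pixels is taken
  verbatim (the shipped experiment table carries one per condition);
* *model mode* — sigma is derived from the dendritic-field power law via a
  retinal magnification constant and a diameter-to-sigma factor.  The two
  constants are exposed and documented as approximate; reproduction mode
  bypasses them entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ViewingGeometry",
    "ReceptiveFieldProfile",
    "pixels_per_degree",
    "dendritic_diameter_um",
    "sigma_f_for",
    "DEFAULT_SURROUND_RATIO",
    "DEFAULT_MAGNIFICATION_MM_PER_DEG",
    "DEFAULT_DIAMETER_TO_SIGMA",
]

#: Fixed centre-to-surround sigma ratio K = sigma_B / sigma_F.
DEFAULT_SURROUND_RATIO = 5.0

#: Approximate linear retinal magnification near the posterior pole (mm of
#: retina per degree of visual angle).  Used only in model mode.
DEFAULT_MAGNIFICATION_MM_PER_DEG = 0.29

#: Conversion from dendritic-field *diameter* to Gaussian sigma; half the
#: diameter is treated as one standard deviation.  Used only in model mode.
DEFAULT_DIAMETER_TO_SIGMA = 0.5


def pixels_per_degree(distance_cm: float, pitch_mm: float) -> float:
    """Pixels per degree of visual angle for a flat screen seen frontally.

    Parameters
    ----------
    distance_cm:
        Viewing distance from eye to screen, in centimetres.
    pitch_mm:
        Width of one pixel on the screen, in millimetres.

    Returns
    -------
    float
        Pixels subtending one degree of visual angle at the screen centre,
        ``1 / degrees(atan(pitch_mm / (10 * distance_cm)))``.  The exact
        arctangent is used; at typical viewing distances the small-angle
        approximation differs by less than 1e-6 relative.
    """
    if not (distance_cm > 0):
        raise ValueError(f"viewing distance must be positive, got {distance_cm}")
    if not (pitch_mm > 0):
        raise ValueError(f"pixel pitch must be positive, got {pitch_mm}")
    deg_per_px = math.degrees(math.atan(pitch_mm / (10.0 * distance_cm)))
    return 1.0 / deg_per_px


@dataclass(frozen=True)
class ViewingGeometry:
    """Screen/eye configuration.

    Attributes
    ----------
    viewing_distance_cm:
        Eye-to-screen distance (cm).
    pixel_pitch_mm:
        Size of one pixel on the monitor (mm); 0.282 mm for the monitor all
        shipped experiment conditions assume.
    pixels_per_degree:
        Derived px/deg (may be overridden to reproduce a printed value
        exactly; by default computed from distance and pitch).
    """

    viewing_distance_cm: float
    pixel_pitch_mm: float = 0.282
    pixels_per_degree: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pixels_per_degree is None:
            object.__setattr__(
                self,
                "pixels_per_degree",
                pixels_per_degree(self.viewing_distance_cm, self.pixel_pitch_mm),
            )
        if not (self.pixels_per_degree > 0):
            raise ValueError("pixels_per_degree must be positive")

    def deg_to_px(self, degrees_va: float) -> float:
        """Angular extent (deg) -> length on screen (px)."""
        return degrees_va * self.pixels_per_degree

    def px_to_deg(self, px: float) -> float:
        """Length on screen (px) -> angular extent (deg)."""
        return px / self.pixels_per_degree

    def arcmin_to_px(self, arcmin: float) -> float:
        """Angular extent (minutes of visual angle) -> px."""
        return self.deg_to_px(arcmin / 60.0)


@dataclass(frozen=True)
class ReceptiveFieldProfile:
    """Centre/surround Gaussian scales at one eccentricity.

    ``sigma_b`` is always ``surround_ratio * sigma_f`` — the surround is a
    fixed multiple of the centre.
    """

    eccentricity_deg: float
    sigma_f: float  # px
    surround_ratio: float = DEFAULT_SURROUND_RATIO

    def __post_init__(self) -> None:
        if not (self.eccentricity_deg >= 0):
            raise ValueError("eccentricity must be >= 0")
        if not (self.sigma_f > 0):
            raise ValueError("sigma_f must be positive")
        if not (self.surround_ratio >= 1):
            raise ValueError("surround ratio K must be >= 1")

    @property
    def sigma_b(self) -> float:
        """Surround sigma in pixels (= K * sigma_f, exactly)."""
        return self.surround_ratio * self.sigma_f


def dendritic_diameter_um(ecc_mm):
    """Midget-cell dendritic field diameter (µm) at a retinal eccentricity (mm).

    Power-law fit to anatomical measurements: ``8.64 * ecc_mm ** 1.04``.
    Strictly increasing and zero at the origin.  Accepts scalars or arrays.
    """
    ecc = np.asarray(ecc_mm, dtype=float)
    if np.any(ecc < 0):
        raise ValueError("retinal eccentricity must be >= 0")
    out = 8.64 * ecc**1.04
    return float(out) if np.isscalar(ecc_mm) else out


def sigma_f_for(
    ecc_deg: float,
    geometry: ViewingGeometry,
    *,
    sigma_px: float | None = None,
    surround_ratio: float = DEFAULT_SURROUND_RATIO,
    magnification_mm_per_deg: float | None = None,
    diameter_to_sigma: float | None = None,
) -> ReceptiveFieldProfile:
    """Receptive-field profile at an eccentricity.

    If ``sigma_px`` is given (reproduction mode) it is used verbatim.
    Otherwise both model constants must be supplied (or left ``None`` to
    request the documented defaults explicitly via
    :data:`DEFAULT_MAGNIFICATION_MM_PER_DEG` /
    :data:`DEFAULT_DIAMETER_TO_SIGMA`): the eccentricity is mapped to
    retinal mm, the dendritic diameter is evaluated there, halved into a
    sigma, converted back to degrees and then to pixels.
    """
    if sigma_px is not None:
        return ReceptiveFieldProfile(ecc_deg, float(sigma_px), surround_ratio)
    mag = (
        DEFAULT_MAGNIFICATION_MM_PER_DEG
        if magnification_mm_per_deg is None
        else magnification_mm_per_deg
    )
    d2s = DEFAULT_DIAMETER_TO_SIGMA if diameter_to_sigma is None else diameter_to_sigma
    if not (mag > 0 and d2s > 0):
        raise ValueError("model-mode constants must be positive")
    ecc_mm = ecc_deg * mag
    diam_um = dendritic_diameter_um(ecc_mm)
    sigma_deg = d2s * (diam_um / 1000.0) / mag
    sigma = sigma_deg * geometry.pixels_per_degree
    if not (sigma > 0):
        raise ValueError(
            "model mode produced a non-positive sigma; supply sigma_px "
            "explicitly for foveal (zero-eccentricity) conditions"
        )
    return ReceptiveFieldProfile(ecc_deg, sigma, surround_ratio)
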