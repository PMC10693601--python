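"""Gaussian profile fitting and geometric rulers.

A sub-diffraction cluster images as (approximately) the microscope PSF, so
its intensity profile along either axis is Gaussian; the fitted FWHM serves
as the cluster's apparent diameter, from which a circular surface area
follows.  Rulers convert dsDNA base pairs to contour length (0.34 nm/bp) and
to the number of protein protomers the fragment can host (one footprint per
``footprint_bp``, default 10 bp from the crystal structure of the
HIN-domain-dsDNA complex).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "GaussianProfileFit",
    "GaussianProfiler",
    "fit_profile",
    "profile_from_image",
    "area_from_fwhm",
    "diameter_from_area",
    "dna_contour_length",
    "protomer_capacity",
    "FWHM_PER_SIGMA",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
BP_TO_NM = 0.34


@dataclass
class GaussianProfileFit:
    amplitude: float
    center_nm: float
    fwhm_nm: float
    offset: float
    rss: float
    success: bool = True

    def __post_init__(self) -> None:
        if self.success and self.fwhm_nm <= 0:
            raise ValueError("fwhm must be > 0")

    @property
    def sigma_nm(self) -> float:
        return self.fwhm_nm / FWHM_PER_SIGMA


class GaussianProfiler(BaseEstimator):
    """Least-squares Gaussian + constant offset fit to an intensity profile.

    ``fit(positions_nm, intensities)`` sets ``amplitude_``, ``center_nm_``,
    ``fwhm_nm_``, ``offset_``, ``rss_``.  Non-convergence sets
    ``success_ = False`` instead of raising.
    """

    def __init__(self, maxfev: int = 20000):
        self.maxfev = maxfev

    def fit(self, positions_nm, intensities):
        x = np.asarray(positions_nm, dtype=float).ravel()
        y = np.asarray(intensities, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("positions and intensities differ in length")
        if x.size < 5:
            raise ValueError(f"need >= 5 points, got {x.size}")
        if np.ptp(y) == 0:
            raise ValueError("constant profile: no peak to fit")
        c0 = float(y.min())
        a0 = float(y.max() - c0)
        mu0 = float(x[np.argmax(y)])
        # moment-based width guess
        w = np.clip(y - c0, 0, None)
        sd0 = float(np.sqrt(np.average((x - mu0) ** 2, weights=w) or 1.0))
        sd0 = max(sd0, float(np.min(np.diff(np.sort(x))) or 1.0))
        try:
            popt, _ = curve_fit(
                lambda xx, a, mu, sd, c: a * np.exp(-((xx - mu) ** 2) / (2 * sd**2)) + c,
                x, y, p0=[a0, mu0, sd0, c0],
                bounds=([0.0, x.min() - np.ptp(x), 1e-9, -np.inf],
                        [np.inf, x.max() + np.ptp(x), np.inf, np.inf]),
                maxfev=self.maxfev,
            )
            a, mu, sd, c = popt
            resid = y - (a * np.exp(-((x - mu) ** 2) / (2 * sd**2)) + c)
            self.amplitude_, self.center_nm_ = float(a), float(mu)
            self.fwhm_nm_ = float(FWHM_PER_SIGMA * sd)
            self.offset_, self.rss_ = float(c), float(np.sum(resid**2))
            self.success_ = True
        except RuntimeError:
            self.amplitude_ = self.center_nm_ = self.fwhm_nm_ = self.offset_ = np.nan
            self.rss_ = np.nan
            self.success_ = False
        return self

    def fit_predict(self, positions_nm, intensities) -> GaussianProfileFit:
        self.fit(positions_nm, intensities)
        return GaussianProfileFit(
            amplitude=self.amplitude_,
            center_nm=self.center_nm_,
            fwhm_nm=self.fwhm_nm_ if self.success_ else np.nan,
            offset=self.offset_,
            rss=self.rss_,
            success=self.success_,
        )


def fit_profile(positions_nm, intensities) -> GaussianProfileFit:
    """Fit a Gaussian + offset to an intensity-vs-position profile."""
    return GaussianProfiler().fit_predict(positions_nm, intensities)


def profile_from_image(image, roi=None, axis: str = "x", pixel_size_nm: float = 100.0):
    """Mean-intensity profile of a (ROI of a) 2D scan along one axis.

    ``axis='x'`` averages rows (profile vs column position); ``axis='y'``
    averages columns.  ``roi`` is (row0, col0, height, width), 0-based.
    Returns (positions_nm at pixel centers, mean intensities).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    if roi is not None:
        r0, c0, h, w = roi
        if r0 < 0 or c0 < 0 or r0 + h > img.shape[0] or c0 + w > img.shape[1]:
            raise ValueError("ROI outside the image")
        img = img[r0 : r0 + h, c0 : c0 + w]
    if axis == "x":
        prof = img.mean(axis=0)
    elif axis == "y":
        prof = img.mean(axis=1)
    else:
        raise ValueError("axis must be 'x' or 'y'")
    pos = (np.arange(prof.size) + 0.5) * pixel_size_nm
    return pos, prof


def area_from_fwhm(fwhm_nm: float) -> float:
    """Circular surface area (um^2) using the FWHM as the diameter."""
    if fwhm_nm <= 0:
        raise ValueError(f"fwhm must be > 0, got {fwhm_nm}")
    radius_um = fwhm_nm / 2.0 * 1e-3
    return float(np.pi * radius_um**2)


def diameter_from_area(area_um2: float) -> float:
    """Diameter (nm) of a circle with the given area (um^2)."""
    if area_um2 <= 0:
        raise ValueError(f"area must be > 0, got {area_um2}")
    return float(2.0 * np.sqrt(area_um2 / np.pi) * 1e3)


def dna_contour_length(bp: float) -> float:
    """dsDNA contour length in nm (0.34 nm per base pair)."""
    if bp < 0:
        raise ValueError("base pairs must be >= 0")
    return float(bp) * BP_TO_NM


def protomer_capacity(bp: float, footprint_bp: float = 10.0) -> int:
    """Number of protein protomers a dsDNA fragment can host.

    One protomer per ``footprint_bp`` base pairs (default 10 bp, the
    crystal-structure footprint of one HIN domain), floored to an integer.
    """
    if bp < 0:
        raise ValueError("base pairs must be >= 0")
    if footprint_bp <= 0:
        raise ValueError("footprint must be > 0")
    return int(np.floor(bp / footprint_bp))
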