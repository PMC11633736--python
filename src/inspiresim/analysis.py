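"""Image-analysis recipes for cross-modality vibrational images.

Covers the downstream quantification chain: per-wavenumber power
normalization of IR images, per-pixel non-negative least-squares
spectral unmixing against reference responses, Pearson-correlation
specificity scoring, ratiometric imaging with the
background-subtract / normalize / add-one recipe, droplet extraction
(bilinear upsampling to a 0.1-um raster, thresholding, connected
components, circularity filtering) with two-sample t and variance
tests, and bead-profile resolution measurement by Gaussian fitting and
quadrature deconvolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import curve_fit, nnls
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .phantoms import BandSpectrum, evaluate_spectrum

__all__ = [
    "UnmixReferences",
    "references_from_library",
    "power_normalize",
    "unmix",
    "pcc",
    "ratiometric",
    "extract_droplets",
    "droplet_stats",
    "significance_stars",
    "fit_profile_fwhm",
    "deconvolve_bead",
    "ProfileFitError",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

# Circularity ceiling absorbing discretization overshoot of 4*pi*A/P^2.
CIRCULARITY_CLIP = 1.05


class ProfileFitError(RuntimeError):
    """Raised when a line-profile Gaussian fit cannot converge."""


@dataclass(frozen=True)
class UnmixReferences:
    """Reference response matrix for spectral unmixing.

    matrix has shape (n_channels, n_species): entry (c, s) is the
    response of pure species s in acquisition channel c (a wavenumber +
    modality pair). Must be non-negative and of full column rank.
    """

    matrix: np.ndarray
    channels: tuple
    species: tuple

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2:
            raise ValueError("reference matrix must be 2-D")
        if m.shape != (len(self.channels), len(self.species)):
            raise ValueError("matrix shape must be (n_channels, n_species)")
        if np.any(m < 0):
            raise ValueError("reference responses must be non-negative")
        if np.linalg.matrix_rank(m) < len(self.species):
            raise ValueError("reference matrix is rank-deficient")


def references_from_library(
    library: dict[str, BandSpectrum],
    channels,
    species=None,
) -> UnmixReferences:
    """Build unmixing references from species band spectra.

    channels: sequence of (wavenumber, modality) acquisition channels.
    """
    if species is None:
        species = list(library)
    mat = np.array(
        [
            [evaluate_spectrum(library[s], nu, modality) for s in species]
            for (nu, modality) in channels
        ]
    )
    return UnmixReferences(mat, tuple(channels), tuple(species))


def power_normalize(ir_image: np.ndarray, power_reference: float) -> np.ndarray:
    """Divide an IR image by the excitation power at its wavenumber.

    power_reference is the source power (mW) at the acquisition
    wavenumber, e.g. interpolated from a per-wavenumber power curve.
    """
    if power_reference <= 0:
        raise ValueError("reference power must be positive")
    return np.asarray(ir_image, dtype=float) / power_reference


def unmix(images: np.ndarray, refs: UnmixReferences):
    """Per-pixel non-negative least squares abundance estimation.

    images: stack of channel images, shape (n_channels, ny, nx) in the
    same channel order as refs. Returns (abundances, residual_norm)
    with shapes (n_species, ny, nx) and (ny, nx).
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3:
        raise ValueError("images must have shape (n_channels, ny, nx)")
    n_ch, ny, nx = images.shape
    if n_ch != refs.matrix.shape[0]:
        raise ValueError("channel count mismatch with references")
    if n_ch < len(refs.species):
        raise ValueError("need at least as many channels as species")
    flat = images.reshape(n_ch, -1)
    n_species = len(refs.species)
    ab = np.empty((n_species, flat.shape[1]))
    res = np.empty(flat.shape[1])
    for p in range(flat.shape[1]):
        ab[:, p], res[p] = nnls(refs.matrix, flat[:, p])
    return ab.reshape(n_species, ny, nx), res.reshape(ny, nx)


def pcc(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Pearson's correlation coefficient over all pixels."""
    a = np.asarray(image_a, dtype=float).ravel()
    b = np.asarray(image_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must share shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant image: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _normalize_unit(img: np.ndarray, background: float) -> np.ndarray:
    out = np.asarray(img, dtype=float) - background
    np.clip(out, 0.0, None, out=out)
    top = out.max()
    if top == 0:
        return out  # zero image maps to zero
    return out / top


def ratiometric(
    numerator_image: np.ndarray,
    denominator_image: np.ndarray,
    background: float | tuple[float, float] | np.ndarray = 0.0,
) -> np.ndarray:
    """Ratiometric image with near-zero-safe normalization.

    Each input is background-subtracted, rescaled to [0, 1] by its
    maximum, and offset by 1 before dividing, bounding the output to
    [0.5, 2]:  out = (norm(A - bgA) + 1) / (norm(B - bgB) + 1).
    background may be a scalar (shared), a (bgA, bgB) pair, or a boolean
    mask whose mean intensity in each image is used.
    """
    a = np.asarray(numerator_image, dtype=float)
    b = np.asarray(denominator_image, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share shape")
    if isinstance(background, np.ndarray) and background.dtype == bool:
        bg_a = float(a[background].mean())
        bg_b = float(b[background].mean())
    elif np.isscalar(background):
        bg_a = bg_b = float(background)
    else:
        bg_a, bg_b = (float(v) for v in background)
    na = _normalize_unit(a, bg_a)
    nb = _normalize_unit(b, bg_b)
    if na.max() == 0 or nb.max() == 0:
        raise ValueError("all-background image: ratio undefined")
    return (na + 1.0) / (nb + 1.0)


# ---------------------------------------------------------------------------
# Droplet morphometry
# ---------------------------------------------------------------------------


def extract_droplets(
    image: np.ndarray,
    pixel_size: float,
    circularity_range: tuple[float, float] = (0.8, 1.0),
    min_diameter: float = 0.4,
    interp_pixel: float = 0.1,
    background: float | None = None,
    threshold: float | str = "otsu",
) -> pd.DataFrame:
    """Extract droplet-like objects and measure size and intensity.

    Pipeline: bilinear interpolation to ``interp_pixel`` (0.1 um)
    raster -> background subtraction (default: image median) ->
    threshold (Otsu by default, or a fixed value) -> 8-connected
    components -> filter by circularity (4 pi A / P^2, Crofton
    perimeter, clipped at 1.05 so discretization overshoot above an
    upper bound of 1.0 is retained) and by minimum equivalent diameter
    (default 0.4 um, the order of the resolution limit).

    Lengths are micrometres. Returns one row per retained droplet:
    centroid_x_um, centroid_y_um, area_um2, equivalent_diameter_um,
    mean_intensity, circularity. An image with no components yields an
    empty table, not an error.
    """
    img = np.asarray(image, dtype=float)
    if pixel_size <= 0 or interp_pixel <= 0:
        raise ValueError("pixel sizes must be positive")
    zoom = pixel_size / interp_pixel
    if abs(zoom - 1.0) > 1e-12:
        img = ndimage.zoom(img, zoom, order=1, grid_mode=True, mode="nearest")
    bg = float(np.median(img)) if background is None else float(background)
    img = np.clip(img - bg, 0.0, None)
    cols = [
        "centroid_x_um",
        "centroid_y_um",
        "area_um2",
        "equivalent_diameter_um",
        "mean_intensity",
        "circularity",
    ]
    if img.max() == 0:
        return pd.DataFrame(columns=cols)
    if threshold == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    binary = img > thr
    if not binary.any():
        return pd.DataFrame(columns=cols)
    labels = label(binary, connectivity=2)
    px_area = interp_pixel**2
    rows = []
    for rp in regionprops(labels, intensity_image=img):
        area = rp.area * px_area
        eq_diam = 2.0 * math.sqrt(area / math.pi)
        perim = rp.perimeter_crofton * interp_pixel
        circ = CIRCULARITY_CLIP if perim == 0 else min(
            4.0 * math.pi * area / perim**2, CIRCULARITY_CLIP
        )
        lo, hi = circularity_range
        hi_eff = hi + (CIRCULARITY_CLIP - 1.0) if hi >= 1.0 else hi
        if not lo <= circ <= hi_eff:
            continue
        if eq_diam < min_diameter:
            continue
        cy, cx = rp.centroid
        rows.append(
            {
                "centroid_x_um": (cx + 0.5) * interp_pixel,
                "centroid_y_um": (cy + 0.5) * interp_pixel,
                "area_um2": area,
                "equivalent_diameter_um": eq_diam,
                "mean_intensity": rp.intensity_mean,
                "circularity": circ,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def significance_stars(p: float) -> str:
    """Star coding of a p-value (thresholds 0.05, 0.01, 1e-3, 1e-4)."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def droplet_stats(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    column: str = "equivalent_diameter_um",
) -> dict:
    """Two-sample comparison of a droplet measurement column.

    Pooled-variance two-sample t test (two-sided) and a two-sided F test
    of equal variances. Returns the statistics, p-values, sample sizes
    and star codes.
    """
    for t in (table_a, table_b):
        if column not in t.columns:
            raise KeyError(f"column {column!r} missing from droplet table")
        if len(t) < 2:
            raise ValueError("each table needs at least 2 rows")
    a = table_a[column].to_numpy(dtype=float)
    b = table_b[column].to_numpy(dtype=float)
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=True)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0 and va == 0:
        f_stat, f_p = 1.0, 1.0
    elif vb == 0:
        f_stat, f_p = math.inf, 0.0
    else:
        f_stat = va / vb
        cdf = stats.f.cdf(f_stat, len(a) - 1, len(b) - 1)
        f_p = 2.0 * min(cdf, 1.0 - cdf)
    return {
        "t_statistic": float(t_stat),
        "t_pvalue": float(t_p),
        "t_stars": significance_stars(float(t_p)),
        "variance_ratio": float(f_stat),
        "variance_pvalue": float(f_p),
        "variance_stars": significance_stars(float(f_p)),
        "n_a": len(a),
        "n_b": len(b),
    }


# ---------------------------------------------------------------------------
# Resolution measurement
# ---------------------------------------------------------------------------


def fit_profile_fwhm(
    image: np.ndarray,
    pixel_size: float,
    axis: str = "x",
    through: tuple[int, int] | None = None,
) -> float:
    """FWHM (nm) of a Gaussian fitted to a line profile.

    The profile runs along ``axis`` through ``through`` (default: the
    image maximum). pixel_size is in micrometres; the returned FWHM is
    in nanometres. Raises ProfileFitError for flat or non-peaked
    profiles.
    """
    img = np.asarray(image, dtype=float)
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if through is None:
        through = np.unravel_index(np.argmax(img), img.shape)
    y0, x0 = through
    profile = img[y0, :] if axis == "x" else img[:, x0]
    if np.ptp(profile) == 0:
        raise ProfileFitError("flat profile: no peak to fit")
    pos = np.arange(profile.size) * pixel_size * 1e3  # nm
    amp0 = profile.max() - profile.min()
    mu0 = pos[np.argmax(profile)]
    sigma0 = max(pixel_size * 1e3, np.sum(profile > profile.min() + amp0 / 2)
                 * pixel_size * 1e3 / FWHM_PER_SIGMA)

    def gauss(xv, amp, mu, sigma, offset):
        return amp * np.exp(-0.5 * ((xv - mu) / sigma) ** 2) + offset

    try:
        popt, _ = curve_fit(
            gauss,
            pos,
            profile,
            p0=(amp0, mu0, sigma0, profile.min()),
            maxfev=10000,
        )
    except RuntimeError as e:
        raise ProfileFitError(f"Gaussian fit did not converge: {e}") from e
    amp, _, sigma, _ = popt
    if amp <= 0 or not np.isfinite(sigma):
        raise ProfileFitError(
            f"degenerate fit (amplitude {amp:.3g}, sigma {sigma:.3g})"
        )
    return float(abs(sigma) * FWHM_PER_SIGMA)


def deconvolve_bead(measured_fwhm: float, bead_diameter: float) -> float:
    """Quadrature-deconvolve a bead's finite size from a measured FWHM.

    Treats the bead as a Gaussian-equivalent object of FWHM equal to its
    diameter: resolution = sqrt(measured^2 - bead^2) (nm). Returns 0
    with a warning when the measured width does not exceed the bead.
    """
    if measured_fwhm < 0 or bead_diameter < 0:
        raise ValueError("widths must be non-negative")
    if measured_fwhm <= bead_diameter:
        if measured_fwhm < bead_diameter:
            warnings.warn(
                "measured FWHM below bead diameter; returning 0", stacklevel=2
            )
        return 0.0
    return float(math.sqrt(measured_fwhm**2 - bead_diameter**2))
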