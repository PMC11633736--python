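"""Forward optics: concentration maps -> focal contrast amplitudes.

Two contrasts are rendered per pixel, each blurred by its own channel
point-spread function:

* ``delta_srl`` -- per-pulse fractional probe loss from stimulated Raman
  loss, bilinear in pump and Stokes power and linear in concentration.
* ``delta_pt`` -- photothermal fractional transmission-modulation depth
  from pulsed mid-IR heating, linear in average IR power and
  concentration.

PSFs are normalized Gaussians; the Raman channel's pump x Stokes focal
product and the photothermal channel's thermal-diffusion blur are both
absorbed into the configured FWHMs (defaults 398 nm and 561 nm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .phantoms import BandSpectrum, ConcentrationMap, evaluate_spectrum

__all__ = [
    "PSFModel",
    "ExcitationConfig",
    "ContrastPair",
    "gaussian_kernel",
    "render_contrast",
    "QCL_RANGE",
    "SMALL_SIGNAL_LIMIT",
]

# Mid-IR source tuning range, cm^-1.
QCL_RANGE = (915.0, 2335.0)
# Fractional modulation above which the small-signal model is unreliable.
SMALL_SIGNAL_LIMIT = 0.2

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def gaussian_kernel(fwhm: float, pixel_size: float, trunc: float = 4.0) -> np.ndarray:
    """Normalized 2-D Gaussian kernel (sum = 1).

    fwhm and pixel_size share any length unit; sigma = fwhm / (2 sqrt(2 ln 2)).
    If fwhm < pixel_size the kernel is unresolvable on the raster: a warning
    is issued and a 1x1 delta kernel returned.
    """
    if fwhm <= 0 or pixel_size <= 0:
        raise ValueError("fwhm and pixel_size must be positive")
    if fwhm < pixel_size:
        warnings.warn(
            f"PSF fwhm {fwhm} below pixel size {pixel_size}; using delta kernel",
            stacklevel=2,
        )
        return np.ones((1, 1))
    sigma = fwhm * FWHM_TO_SIGMA / pixel_size
    radius = max(1, int(math.ceil(trunc * sigma)))
    x = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(x, x)
    k = np.exp(-0.5 * (xx**2 + yy**2) / sigma**2)
    return k / k.sum()


@dataclass(frozen=True)
class PSFModel:
    """Gaussian channel PSF; fwhm in nanometres."""

    fwhm: float
    trunc: float = 4.0

    def kernel(self, pixel_size_um: float) -> np.ndarray:
        return gaussian_kernel(self.fwhm, pixel_size_um * 1e3, self.trunc)


@dataclass(frozen=True)
class ExcitationConfig:
    """Beam settings: wavenumbers in cm^-1, average powers in mW."""

    ir_wavenumber: float
    raman_wavenumber: float
    p_pump: float = 140.0
    p_stokes: float = 140.0
    p_ir: float = 5.0

    def __post_init__(self):
        if min(self.p_pump, self.p_stokes, self.p_ir) < 0:
            raise ValueError("powers must be non-negative")
        lo, hi = QCL_RANGE
        if not lo <= self.ir_wavenumber <= hi:
            raise ValueError(
                f"ir_wavenumber {self.ir_wavenumber} outside QCL range {QCL_RANGE}"
            )
        if self.raman_wavenumber <= 0:
            raise ValueError("raman_wavenumber must be positive")


@dataclass
class ContrastPair:
    """Per-pixel modulation depths sharing the source map's raster."""

    delta_srl: np.ndarray
    delta_pt: np.ndarray
    pixel_size: float

    def __post_init__(self):
        self.delta_srl = np.asarray(self.delta_srl, dtype=float)
        self.delta_pt = np.asarray(self.delta_pt, dtype=float)
        if self.delta_srl.shape != self.delta_pt.shape:
            raise ValueError("delta maps must share shape")


def _blur(channel_sum: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    if kernel.shape == (1, 1):
        return channel_sum * kernel[0, 0]
    return convolve(channel_sum, kernel, mode="reflect")


def render_contrast(
    cmap: ConcentrationMap,
    library: dict[str, BandSpectrum],
    psf_raman: PSFModel,
    psf_ir: PSFModel,
    exc: ExcitationConfig,
    gains: tuple[float, float],
    clip: bool = True,
) -> ContrastPair:
    """Render SRL and photothermal modulation-depth maps.

    delta_srl = k_srl * p_pump * p_stokes * sum_s [C_s (*) PSF_raman] * R_s(nu_R)
    delta_pt  = k_pt  * p_ir             * sum_s [C_s (*) PSF_ir]    * A_s(nu_IR)

    where R_s / A_s are the species Raman / IR spectra evaluated at the
    respective excitation wavenumbers, and (*) is reflective-boundary
    convolution with a unit-sum kernel (so total signal is conserved).
    Values above the small-signal limit (0.2) are clipped with a warning.
    """
    missing = [s for s in cmap.species_names if s not in library]
    if missing:
        raise KeyError(f"library missing species {missing}")
    k_srl, k_pt = gains
    kern_r = psf_raman.kernel(cmap.pixel_size)
    kern_i = psf_ir.kernel(cmap.pixel_size)
    srl = np.zeros(cmap.shape)
    pt = np.zeros(cmap.shape)
    for i, name in enumerate(cmap.species_names):
        spec = library[name]
        r_amp = evaluate_spectrum(spec, exc.raman_wavenumber, "raman")
        i_amp = evaluate_spectrum(spec, exc.ir_wavenumber, "ir")
        if r_amp:
            srl += _blur(cmap.grid[i], kern_r) * r_amp
        if i_amp:
            pt += _blur(cmap.grid[i], kern_i) * i_amp
    srl *= k_srl * exc.p_pump * exc.p_stokes
    pt *= k_pt * exc.p_ir
    if clip:
        for name, arr in (("delta_srl", srl), ("delta_pt", pt)):
            top = arr.max(initial=0.0)
            if top > SMALL_SIGNAL_LIMIT:
                warnings.warn(
                    f"{name} reaches {top:.3g} > {SMALL_SIGNAL_LIMIT}; clipping "
                    "(small-signal model validity limit)",
                    stacklevel=2,
                )
                np.clip(arr, None, SMALL_SIGNAL_LIMIT, out=arr)
    return ContrastPair(srl, pt, cmap.pixel_size)
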