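"""Synthetic specimens for the virtual microscope.

Provides per-species vibrational band spectra (separate IR and Raman band
lists, reflecting the complementary selection rules: IR activity requires
a change in dipole moment along the normal coordinate, Raman activity a
change in polarizability) and 2-D concentration maps emulating the
specimens used to characterize the instrument: polymer beads, an oil
film, a ternary chemical mixture, and droplet-bearing cell-like fields.

All generators are deterministic under a fixed seed, and the droplet
field returns its ground-truth object table so downstream segmentation
can be scored against construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "BandSpectrum",
    "ConcentrationMap",
    "PlacementError",
    "evaluate_spectrum",
    "make_bead_map",
    "make_mixture_map",
    "make_droplet_field",
    "uniform_map",
    "species_preset",
    "SPECIES_PRESETS",
]

Modality = Literal["ir", "raman"]

# Retry budget for rejection-sampled, non-overlapping object placement.
DEFAULT_PLACEMENT_RETRIES = 1000


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without overlap.

    Carries ``placed``, the number of objects successfully placed before
    the retry budget was exhausted.
    """

    def __init__(self, message: str, placed: int):
        super().__init__(message)
        self.placed = placed


@dataclass(frozen=True)
class Band:
    """A single vibrational band.

    center, fwhm in cm^-1; amplitude is a relative (dimensionless)
    strength; modality selects the spectrum ("ir" or "raman") the band
    contributes to.
    """

    center: float
    fwhm: float
    amplitude: float
    modality: Modality

    def __post_init__(self):
        if self.center <= 0:
            raise ValueError(f"band center must be > 0, got {self.center}")
        if self.fwhm <= 0:
            raise ValueError(f"band fwhm must be > 0, got {self.fwhm}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")
        if self.modality not in ("ir", "raman"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass(frozen=True)
class BandSpectrum:
    """IR and Raman band lists for one chemical species.

    The two cross-section scale factors carry the (relative) magnitude
    disparity between IR absorption and Raman scattering cross sections;
    they default to 1 so that excitation-gain factors can absorb absolute
    magnitudes.
    """

    species_name: str
    bands: tuple[Band, ...]
    ir_cross_section_scale: float = 1.0
    raman_cross_section_scale: float = 1.0

    def evaluate(self, wavenumbers, modality: Modality, shape: str = "lorentzian"):
        return evaluate_spectrum(self, wavenumbers, modality, shape=shape)


def evaluate_spectrum(
    spectrum: BandSpectrum,
    wavenumbers,
    modality: Modality,
    shape: str = "lorentzian",
):
    """Evaluate a species spectrum on a wavenumber axis.

    Bands are amplitude-normalized line profiles (peak value equals the
    band amplitude): Lorentzian by default,
    ``amp * (fwhm/2)^2 / ((nu - center)^2 + (fwhm/2)^2)``,
    or Gaussian with the same FWHM. The result is the sum over the bands
    of the requested modality, times the modality's cross-section scale.
    """
    if modality not in ("ir", "raman"):
        raise ValueError(f"unknown modality {modality!r}; expected 'ir' or 'raman'")
    if shape not in ("lorentzian", "gaussian"):
        raise ValueError(f"unknown line shape {shape!r}")
    nu = np.atleast_1d(np.asarray(wavenumbers, dtype=float))
    if nu.size > 1 and not np.all(np.diff(nu) > 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    out = np.zeros_like(nu)
    for b in spectrum.bands:
        if b.modality != modality:
            continue
        hw = b.fwhm / 2.0
        if shape == "lorentzian":
            out += b.amplitude * hw**2 / ((nu - b.center) ** 2 + hw**2)
        else:
            sigma = b.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            out += b.amplitude * np.exp(-0.5 * ((nu - b.center) / sigma) ** 2)
    scale = (
        spectrum.ir_cross_section_scale
        if modality == "ir"
        else spectrum.raman_cross_section_scale
    )
    out *= scale
    if np.isscalar(wavenumbers) or np.asarray(wavenumbers).ndim == 0:
        return float(out[0])
    return out


# ---------------------------------------------------------------------------
# Species presets
#
# Band positions follow standard vibrational assignments for each compound
# (C=O stretches near 1700-1750, CH2/CH3 deformations near 1380-1470,
# aromatic ring modes near 1480-1600, diyne C#C near 2216, C-H stretches
# at 2850-2960, amide I/II at 1655/1545, carbohydrate/phosphate modes near
# 1069-1224 cm^-1).  Relative amplitudes are plausible config values, not
# literature cross sections.
# ---------------------------------------------------------------------------


def _spec(name, ir, raman):
    bands = tuple(
        Band(c, w, a, "ir") for (c, w, a) in ir
    ) + tuple(Band(c, w, a, "raman") for (c, w, a) in raman)
    return BandSpectrum(name, bands)


SPECIES_PRESETS: dict[str, BandSpectrum] = {
    # poly(methyl methacrylate): strong ester C=O in IR; CH3 asymmetric
    # stretch dominates the Raman C-H region, with a weak 1459 cm^-1
    # CH deformation (roughly 6x weaker than the 2850-region response).
    "pmma": _spec(
        "pmma",
        ir=[(1730.0, 24.0, 1.0), (1150.0, 40.0, 0.4)],
        raman=[(2957.0, 28.0, 1.0), (2850.0, 26.0, 0.6), (1459.0, 20.0, 0.1)],
    ),
    # oil film: triglyceride ester C=O, CH2 symmetric stretch.
    "oil": _spec(
        "oil",
        ir=[(1750.0, 26.0, 1.0), (1465.0, 20.0, 0.5)],
        raman=[(2850.0, 26.0, 1.0), (2930.0, 30.0, 0.4)],
    ),
    # palmitic acid: carboxylic C=O at 1700 (IR-exclusive channel),
    # CH2 scissoring near 1465 overlapping the 1477 cm^-1 IR channel.
    "palmitic_acid": _spec(
        "palmitic_acid",
        ir=[(1700.0, 20.0, 1.0), (1465.0, 18.0, 0.5)],
        raman=[(2850.0, 24.0, 1.0), (1440.0, 22.0, 0.35)],
    ),
    # 1,4-diphenylbutadiyne: diyne C#C stretch (Raman-exclusive) and
    # aromatic ring mode at 1593, Raman-dominant with weak IR activity.
    "diphenylbutadiyne": _spec(
        "diphenylbutadiyne",
        ir=[(1593.0, 14.0, 0.15)],
        raman=[(2216.0, 12.0, 1.0), (1593.0, 14.0, 0.8)],
    ),
    # triphenylphosphine: aromatic P-phenyl ring modes; 1477 is the
    # IR-exclusive channel; a Raman ring mode near 1587 overlaps the
    # 1593 cm^-1 Raman channel.
    "triphenylphosphine": _spec(
        "triphenylphosphine",
        ir=[(1477.0, 14.0, 1.0), (1435.0, 16.0, 0.6)],
        raman=[(1587.0, 14.0, 0.3), (1000.0, 10.0, 0.5)],
    ),
    # generic biological components used for cell/tissue-like phantoms
    "lipid": _spec(
        "lipid",
        ir=[(1750.0, 26.0, 1.0), (1465.0, 20.0, 0.6)],
        raman=[(2850.0, 26.0, 1.0), (2870.0, 24.0, 0.4)],
    ),
    "protein": _spec(
        "protein",
        ir=[(1655.0, 30.0, 1.0), (1545.0, 30.0, 0.7), (1224.0, 30.0, 0.2)],
        raman=[(2930.0, 30.0, 1.0), (2870.0, 24.0, 0.5)],
    ),
    "proteoglycan": _spec(
        "proteoglycan",
        ir=[(1080.0, 30.0, 1.0), (1069.0, 24.0, 0.5)],
        raman=[(2930.0, 30.0, 0.3)],
    ),
    "cholesterol": _spec(
        "cholesterol",
        ir=[(1375.0, 18.0, 0.5), (1465.0, 18.0, 0.8)],
        raman=[(2870.0, 24.0, 1.0)],
    ),
}


def species_preset(name: str) -> BandSpectrum:
    """Return the preset band spectrum for a named species."""
    try:
        return SPECIES_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"no preset for species {name!r}; available: {sorted(SPECIES_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Concentration maps
# ---------------------------------------------------------------------------


@dataclass
class ConcentrationMap:
    """Per-species non-negative concentration grids on a common pixel raster.

    grid has shape (n_species, ny, nx); pixel_size is in micrometres.
    The origin convention is pixel-center, index (0, 0) at top-left,
    x fastest-varying.
    """

    species_names: list[str]
    grid: np.ndarray
    pixel_size: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("grid must have shape (n_species, ny, nx)")
        if len(self.species_names) != self.grid.shape[0]:
            raise ValueError("species_names length must match grid pages")
        if np.any(self.grid < 0):
            raise ValueError("concentrations must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape[1:]

    def species(self, name: str) -> np.ndarray:
        return self.grid[self.species_names.index(name)]


def uniform_map(
    species_name: str,
    value: float = 1.0,
    shape: tuple[int, int] = (1, 1),
    pixel_size: float = 1.0,
) -> ConcentrationMap:
    """A spatially uniform single-species map (film-like specimen)."""
    grid = np.full((1, *shape), float(value))
    return ConcentrationMap([species_name], grid, pixel_size)


def _pixel_centers(field: float, pixel_size: float) -> np.ndarray:
    n = int(round(field / pixel_size))
    if n < 1:
        raise ValueError("field must contain at least one pixel")
    # centered raster: coordinates of pixel centers relative to field center
    return (np.arange(n) - (n - 1) / 2.0) * pixel_size


def make_bead_map(
    diameter: float,
    pixel_size: float,
    field: float,
    species_name: str = "pmma",
    profile: str = "sphere",
) -> ConcentrationMap:
    """Render a single centered bead.

    With ``profile="sphere"`` each pixel carries the projected chord
    length of a solid sphere through the pixel center,
    ``2*sqrt(R^2 - r^2)``, normalized to 1 at the bead center -- the
    projected-mass profile of a homogeneous bead, not a flat disk.
    ``profile="gaussian"`` renders an isotropic Gaussian of FWHM equal to
    the diameter (the Gaussian-equivalent bead used by quadrature
    resolution deconvolution).

    diameter, pixel_size and field are in micrometres.
    """
    if diameter < pixel_size:
        raise ValueError("bead diameter must be >= pixel_size")
    if field < diameter:
        raise ValueError(f"field {field} um smaller than bead diameter {diameter} um")
    if profile not in ("sphere", "gaussian"):
        raise ValueError(f"unknown bead profile {profile!r}")
    n = int(round(field / pixel_size))
    # bead centered on a pixel center so the peak value is exactly 1
    x = (np.arange(n) - n // 2) * pixel_size
    xx, yy = np.meshgrid(x, x)
    r2 = xx**2 + yy**2
    R = diameter / 2.0
    if profile == "sphere":
        img = np.sqrt(np.clip(R**2 - r2, 0.0, None)) / R
    else:
        sigma = diameter / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        img = np.exp(-0.5 * r2 / sigma**2)
    return ConcentrationMap([species_name], img[None], pixel_size)


def _place_disks(rng, n, radii, field, retries):
    """Rejection-sample non-overlapping disk centers in a square field."""
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for i in range(n):
        r = radii[i]
        ok = False
        for _ in range(retries):
            cx = rng.uniform(r, field - r)
            cy = rng.uniform(r, field - r)
            if all(
                (cx - px) ** 2 + (cy - py) ** 2 > (r + pr) ** 2
                for (px, py), pr in zip(centers, placed_r)
            ):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place object {i + 1}/{n} without overlap "
                f"after {retries} retries ({i} placed)",
                placed=i,
            )
        centers.append((cx, cy))
        placed_r.append(r)
    return centers


def make_mixture_map(
    species: Sequence[str],
    n_grains: int,
    grain_size: float,
    seed: int,
    pixel_size: float = 0.4,
    field: float | None = None,
    size_jitter: float = 0.2,
    retries: int = DEFAULT_PLACEMENT_RETRIES,
) -> ConcentrationMap:
    """Granular powder mixture: round grains, one species per grain.

    Species are assigned cyclically so grain counts (and hence expected
    total amount per species, for equal grain sizes) are as equal as the
    1:1:...:1 molar mixing ratio allows. Grain diameters are jittered by
    a uniform factor in [1 - size_jitter, 1 + size_jitter].
    """
    if n_grains < 1:
        raise ValueError("n_grains must be >= 1")
    species = list(species)
    rng = np.random.default_rng(seed)
    if field is None:
        # sized so that grains occupy ~20% of the area
        field = math.sqrt(n_grains * math.pi * (grain_size / 2) ** 2 / 0.2)
        field = max(field, 2.0 * grain_size)
    diam = grain_size * rng.uniform(1 - size_jitter, 1 + size_jitter, size=n_grains)
    centers = _place_disks(rng, n_grains, diam / 2.0, field, retries)
    # snap centers to pixel centers: equal-diameter grains then rasterize
    # to identical pixel counts, making the 1:1:1 share exact
    centers = [
        (
            (round(cx / pixel_size - 0.5) + 0.5) * pixel_size,
            (round(cy / pixel_size - 0.5) + 0.5) * pixel_size,
        )
        for (cx, cy) in centers
    ]
    # cyclic assignment over a seeded shuffle of the species order
    order = list(rng.permutation(len(species)))
    assignment = [order[k % len(species)] for k in range(n_grains)]
    x = _pixel_centers(field, pixel_size) + field / 2.0
    xx, yy = np.meshgrid(x, x)
    grid = np.zeros((len(species), x.size, x.size))
    for (cx, cy), d, s in zip(centers, diam, assignment):
        grid[s][(xx - cx) ** 2 + (yy - cy) ** 2 <= (d / 2.0) ** 2] = 1.0
    return ConcentrationMap(species, grid, pixel_size)


def make_droplet_field(
    n_droplets: int,
    size_dist: tuple[float, float] = (1.0, 0.2),
    intensity_dist: tuple[float, float] = (1.0, 0.1),
    circular_fraction: float = 1.0,
    seed: int = 0,
    pixel_size: float = 0.2,
    field: float = 40.0,
    species_name: str = "lipid",
    aspect_range: tuple[float, float] = (3.0, 5.0),
    retries: int = DEFAULT_PLACEMENT_RETRIES,
) -> tuple[ConcentrationMap, pd.DataFrame]:
    """Droplet-bearing field plus its ground-truth object table.

    ``round(n * circular_fraction)`` droplets are rendered as solid disks;
    the remainder as elongated ellipses (aspect ratio >= 3, random
    orientation, area matched to the sampled equivalent diameter). Sizes
    and per-droplet intensities are Gaussian-distributed (truncated to
    stay positive and resolvable). The returned table exactly enumerates
    the rendered objects: columns x_um, y_um (centers, from the field's
    top-left corner), diameter_um (equivalent diameter), intensity,
    shape ("circular" / "elongated").
    """
    if size_dist[0] <= 0 or intensity_dist[0] <= 0:
        raise ValueError("size and intensity distributions must have positive mean")
    if not 0.0 <= circular_fraction <= 1.0:
        raise ValueError("circular_fraction must be in [0, 1]")
    cols = ["x_um", "y_um", "diameter_um", "intensity", "shape"]
    x = _pixel_centers(field, pixel_size) + field / 2.0
    n_px = x.size
    if n_droplets == 0:
        return (
            ConcentrationMap([species_name], np.zeros((1, n_px, n_px)), pixel_size),
            pd.DataFrame(columns=cols),
        )
    rng = np.random.default_rng(seed)
    n_circ = int(round(n_droplets * circular_fraction))
    shapes = ["circular"] * n_circ + ["elongated"] * (n_droplets - n_circ)
    diam = rng.normal(size_dist[0], size_dist[1], size=n_droplets)
    diam = np.clip(diam, 2.0 * pixel_size, None)
    inten = np.clip(rng.normal(intensity_dist[0], intensity_dist[1], n_droplets), 1e-3, None)
    aspect = rng.uniform(*aspect_range, size=n_droplets)
    theta = rng.uniform(0, math.pi, size=n_droplets)
    # exclusion radius: semi-major axis for elongated objects, plus margin
    # so neighbouring objects remain separable after PSF blur
    excl = np.where(
        np.array(shapes) == "circular",
        diam / 2.0,
        diam / 2.0 * np.sqrt(aspect),
    ) + 3.0 * pixel_size
    try:
        centers = _place_disks(rng, n_droplets, excl, field, retries)
    except PlacementError as e:
        raise PlacementError(
            f"droplet density too high for field {field} um: {e}", e.placed
        ) from None
    xx, yy = np.meshgrid(x, x)
    img = np.zeros((n_px, n_px))
    for k, (cx, cy) in enumerate(centers):
        if shapes[k] == "circular":
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= (diam[k] / 2.0) ** 2
        else:
            a = diam[k] / 2.0 * math.sqrt(aspect[k])
            b = diam[k] / 2.0 / math.sqrt(aspect[k])
            u = (xx - cx) * math.cos(theta[k]) + (yy - cy) * math.sin(theta[k])
            v = -(xx - cx) * math.sin(theta[k]) + (yy - cy) * math.cos(theta[k])
            mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[mask] = np.maximum(img[mask], inten[k])
    table = pd.DataFrame(
        {
            "x_um": [c[0] for c in centers],
            "y_um": [c[1] for c in centers],
            "diameter_um": diam,
            "intensity": inten,
            "shape": shapes,
        }
    )
    return ConcentrationMap([species_name], img[None], pixel_size), table
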