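"""Readers/writers and run configuration.

Formats: multi-page 32-bit-float TIFF for images and concentration maps
(pixel size and channel metadata in the ImageDescription tag as JSON),
CSV for spectra and droplet tables, float32 binary with a YAML sidecar
for time traces, YAML for configuration. A run is reproducible from its
serialized configuration and seed alone; every CLI run writes a
provenance record (config hash, seed, version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .demod import SpectrumResult
from .optics import ExcitationConfig, PSFModel
from .phantoms import ConcentrationMap
from .waveform import NoiseConfig, PulseTrainConfig, ThermalConfig, TimeTrace

__all__ = [
    "write_image_tiff",
    "read_image_tiff",
    "write_map_tiff",
    "read_map_tiff",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_trace",
    "read_trace",
    "RunConfig",
    "provenance_record",
]


class TiffMetadataError(ValueError):
    """Malformed or missing metadata tag in a TIFF file."""


def write_image_tiff(
    path,
    stack: np.ndarray,
    pixel_size: float,
    metadata: dict | None = None,
    channel_names: list[str] | None = None,
) -> None:
    """Write a (pages, ny, nx) or (ny, nx) float32 stack with metadata."""
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim == 2:
        stack = stack[None]
    desc = {
        "pixel_size_um": float(pixel_size),
        "channel_names": channel_names or [f"ch{i}" for i in range(stack.shape[0])],
        "metadata": metadata or {},
    }
    tifffile.imwrite(str(path), stack, description=json.dumps(desc))


def read_image_tiff(path):
    """Read a stack written by write_image_tiff.

    Returns (stack, pixel_size_um, channel_names, metadata).
    """
    with tifffile.TiffFile(str(path)) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        if desc is None:
            raise TiffMetadataError(f"{path}: missing ImageDescription tag")
        try:
            meta = json.loads(desc.value)
            pixel_size = float(meta["pixel_size_um"])
            names = list(meta["channel_names"])
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as e:
            raise TiffMetadataError(
                f"{path}: malformed ImageDescription tag ({e})"
            ) from e
    if stack.ndim == 2:
        stack = stack[None]
    return stack, pixel_size, names, meta.get("metadata", {})


def write_map_tiff(path, cmap: ConcentrationMap, metadata: dict | None = None):
    """One TIFF page per species, 32-bit float."""
    write_image_tiff(
        path,
        cmap.grid,
        cmap.pixel_size,
        metadata=metadata,
        channel_names=list(cmap.species_names),
    )


def read_map_tiff(path) -> ConcentrationMap:
    stack, pixel_size, names, _ = read_image_tiff(path)
    return ConcentrationMap(names, stack.astype(float), pixel_size)


def write_spectrum_csv(path, result: SpectrumResult) -> None:
    """Two-block CSV: IR sweep then Raman sweep, 9 significant digits."""
    rows = []
    for nu, v in zip(result.ir_axis, result.ir_values):
        rows.append(("ir", nu, v))
    for nu, v in zip(result.raman_axis, result.raman_values):
        rows.append(("raman", nu, v))
    df = pd.DataFrame(rows, columns=["modality", "wavenumber_cm-1", "intensity"])
    df.to_csv(path, index=False, float_format="%.9g")


def read_spectrum_csv(path) -> SpectrumResult:
    df = pd.read_csv(path)
    parts = {}
    for mod in ("ir", "raman"):
        sub = df[df["modality"] == mod]
        axis = sub["wavenumber_cm-1"].to_numpy(dtype=float)
        if axis.size > 1 and not np.all(np.diff(axis) > 0):
            raise ValueError(f"{path}: non-monotone {mod} wavenumber axis")
        parts[mod] = (axis, sub["intensity"].to_numpy(dtype=float))
    return SpectrumResult(
        ir_axis=parts["ir"][0],
        ir_values=parts["ir"][1],
        raman_axis=parts["raman"][0],
        raman_values=parts["raman"][1],
    )


def write_trace(path, trace: TimeTrace) -> None:
    """float32 binary samples plus a YAML sidecar with full provenance."""
    path = Path(path)
    trace.samples.astype(np.float32).tofile(path)
    sidecar = {
        "sample_rate_hz": trace.sample_rate,
        "n_samples": int(trace.samples.size),
        "dtype": "float32",
        "delta_srl": trace.delta_srl,
        "delta_pt": trace.delta_pt,
        "train": asdict(trace.train) if trace.train else None,
        "thermal": asdict(trace.thermal) if trace.thermal else None,
        "noise": asdict(trace.noise) if trace.noise else None,
    }
    path.with_suffix(path.suffix + ".yaml").write_text(
        yaml.safe_dump(sidecar, sort_keys=False)
    )


def read_trace(path) -> TimeTrace:
    path = Path(path)
    sidecar = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    samples = np.fromfile(path, dtype=np.float32).astype(float)
    if samples.size != sidecar["n_samples"]:
        raise ValueError(
            f"{path}: expected {sidecar['n_samples']} samples, found {samples.size}"
        )
    return TimeTrace(
        samples=samples,
        sample_rate=float(sidecar["sample_rate_hz"]),
        train=PulseTrainConfig(**sidecar["train"]) if sidecar.get("train") else None,
        thermal=ThermalConfig(**sidecar["thermal"]) if sidecar.get("thermal") else None,
        noise=NoiseConfig(**sidecar["noise"]) if sidecar.get("noise") else None,
        delta_srl=float(sidecar.get("delta_srl", 0.0)),
        delta_pt=float(sidecar.get("delta_pt", 0.0)),
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_PHANTOM_DEFAULT = {
    "kind": "uniform",  # uniform | bead | mixture | droplets
    "species": ["oil"],
    "value": 1.0,
    "shape": [16, 16],
    "pixel_size_um": 0.4,
    "diameter_um": 0.5,
    "field_um": 3.0,
    "profile": "sphere",
    "n_grains": 30,
    "grain_size_um": 2.0,
    "n_droplets": 50,
    "size_dist_um": [1.0, 0.2],
    "intensity_dist": [1.0, 0.1],
    "circular_fraction": 0.8,
}


@dataclass
class RunConfig:
    """Serializable bundle of all sub-configurations for one run."""

    phantom: dict = field(default_factory=lambda: dict(_PHANTOM_DEFAULT))
    excitation: ExcitationConfig = field(
        default_factory=lambda: ExcitationConfig(
            ir_wavenumber=1750.0, raman_wavenumber=2850.0
        )
    )
    train: PulseTrainConfig = field(default_factory=PulseTrainConfig)
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    psf_raman: PSFModel = field(default_factory=lambda: PSFModel(fwhm=398.0))
    psf_ir: PSFModel = field(default_factory=lambda: PSFModel(fwhm=561.0))
    gains: tuple[float, float] = (5e-8, 0.0036)
    output_gains: tuple[float, float] = (100.0, 1000.0)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "phantom": dict(self.phantom),
            "excitation": asdict(self.excitation),
            "train": asdict(self.train),
            "thermal": asdict(self.thermal),
            "noise": asdict(self.noise),
            "psf_raman": asdict(self.psf_raman),
            "psf_ir": asdict(self.psf_ir),
            "gains": list(self.gains),
            "output_gains": list(self.output_gains),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = {}
        if "phantom" in d:
            kw["phantom"] = {**_PHANTOM_DEFAULT, **d["phantom"]}
        if "excitation" in d:
            kw["excitation"] = ExcitationConfig(**d["excitation"])
        if "train" in d:
            kw["train"] = PulseTrainConfig(**d["train"])
        if "thermal" in d:
            kw["thermal"] = ThermalConfig(**d["thermal"])
        if "noise" in d:
            kw["noise"] = NoiseConfig(**d["noise"])
        if "psf_raman" in d:
            kw["psf_raman"] = PSFModel(**d["psf_raman"])
        if "psf_ir" in d:
            kw["psf_ir"] = PSFModel(**d["psf_ir"])
        for key in ("gains", "output_gains"):
            if key in d:
                kw[key] = tuple(d[key])
        if "seed" in d:
            kw["seed"] = int(d["seed"])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def provenance_record(config: RunConfig, command: str, seed: int) -> dict:
    return {
        "command": command,
        "seed": seed,
        "config_hash": config.config_hash(),
        "inspiresim_version": __version__,
    }
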