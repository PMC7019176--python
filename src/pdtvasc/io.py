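"""Shared readers/writers, run configuration and provenance records.

Volumes travel as NIfTI-1 (4th axis = flip angle or time) with the affine
carried untouched; microscopy images as TIFF whose pixel size must be
present in the tags or supplied explicitly — never silently defaulted;
tables as CSV with documented column names.  Voxel coordinates are 0-based
with axis order [x, y, z, t] throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .protocol import AifParams, NoiseSpec, ScanProtocol

__all__ = ["save_nifti", "load_nifti", "load_tiff", "save_tiff",
           "RunConfig", "write_provenance"]


def save_nifti(path, data, affine=None, dtype=None) -> None:
    """Write ``data`` as NIfTI-1; identity affine unless one is given."""
    if affine is None:
        affine = np.eye(4)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_nifti(path):
    """Read a NIfTI volume; returns ``(data, affine)`` as float64/float32."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input volume: {path}")
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def save_tiff(path, pixels, pixel_area_um2: float) -> None:
    """Write a TIFF carrying the pixel size in its resolution tags."""
    side_um = float(np.sqrt(pixel_area_um2))
    # TIFF resolution is pixels per unit; use centimeter units.
    px_per_cm = 1e4 / side_um
    tifffile.imwrite(str(path), np.asarray(pixels),
                     resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER")


def load_tiff(path, pixel_area_um2: float | None = None):
    """Read a TIFF image and its pixel area (um^2 per pixel).

    The pixel size is taken from the TIFF resolution tags; when the file
    carries none, ``pixel_area_um2`` must be supplied explicitly or a
    ValueError asks for it (``--pixel-area`` on the CLI).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input image: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        pixels = page.asarray()
        tags = page.tags
        res = tags.get("XResolution")
        unit = tags.get("ResolutionUnit")
        area = None
        if res is not None and res.value[0] not in (0, 1):
            num, den = res.value
            px_per_unit = num / den
            unit_um = {2: 25400.0, 3: 1e4}.get(getattr(unit.value, "value", unit.value) if unit else 2)
            if unit_um is not None and px_per_unit > 0:
                side = unit_um / px_per_unit
                area = side * side
    if area is None:
        area = pixel_area_um2
    if area is None:
        raise ValueError(f"{path} carries no pixel size; pass --pixel-area "
                         "(um^2 per pixel) explicitly")
    return pixels, float(area)


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs, YAML round-trippable."""

    out_dir: str = "run_out"
    seed: int = 0
    protocol: ScanProtocol = field(default_factory=ScanProtocol)
    aif: AifParams = field(default_factory=AifParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    phantom: bool = True            # stage toggles
    shape: tuple[int, int, int] = (64, 64, 17)
    core_volume_fraction: float = 0.3
    vfa_path: str | None = None     # inputs for phantom-less runs
    dce_path: str | None = None
    tumor_mask_path: str | None = None

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "protocol": self.protocol.to_dict(),
            "aif": self.aif.to_dict(),
            "noise": self.noise.to_dict(),
            "phantom": self.phantom,
            "shape": list(self.shape),
            "core_volume_fraction": self.core_volume_fraction,
            "vfa_path": self.vfa_path,
            "dce_path": self.dce_path,
            "tumor_mask_path": self.tumor_mask_path,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["protocol"] = ScanProtocol.from_dict(d.get("protocol", {}))
        d["aif"] = AifParams.from_dict(d.get("aif", {}))
        d["noise"] = NoiseSpec.from_dict(d.get("noise", {}))
        d["shape"] = tuple(d.get("shape", (64, 64, 17)))
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def write_provenance(path, config: RunConfig, extra: dict | None = None) -> None:
    """JSON record of the exact inputs of a run (config, seed, version)."""
    from . import __version__

    record = {"package": "pdtvasc", "version": __version__,
              "seed": config.seed, "config": config.to_dict()}
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))
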