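"""Reading and writing masks and tables.

Masks travel as NIfTI (pixel spacing in the header, preferred) or PNG
(spacing supplied by the run configuration).  Tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .types import VesselMask


def write_mask_nifti(mask: VesselMask, path: str | Path) -> None:
    """Store a 2D mask as a single-slice NIfTI; spacing goes into the
    header zooms (x = column spacing, y = row spacing)."""
    data = mask.raster.astype(np.uint8)[..., np.newaxis]
    affine = np.diag([mask.spacing[1], mask.spacing[0], 1.0, 1.0])
    affine[0, 3], affine[1, 3] = mask.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((mask.spacing[1], mask.spacing[0], 1.0))
    nib.save(img, str(path))


def read_mask_nifti(path: str | Path) -> VesselMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError(f"{path}: expected a single-slice volume, "
                             f"got shape {data.shape}")
        data = data[..., 0]
    zooms = img.header.get_zooms()
    spacing = (float(zooms[1]), float(zooms[0]))   # (row mm, col mm)
    origin = (float(img.affine[0, 3]), float(img.affine[1, 3]))
    return VesselMask(data > 0, spacing, origin)


def write_mask_png(mask: VesselMask, path: str | Path) -> None:
    Image.fromarray((mask.raster * 255).astype(np.uint8)).save(str(path))


def read_mask_png(path: str | Path,
                  spacing: tuple[float, float]) -> VesselMask:
    data = np.asarray(Image.open(str(path)).convert("L"))
    return VesselMask(data > 127, spacing)


def read_mask(path: str | Path,
              spacing: tuple[float, float] | None = None) -> VesselMask:
    """Dispatch on suffix; PNG requires an explicit spacing."""
    path = Path(path)
    if path.suffix in {".nii", ".gz"}:
        return read_mask_nifti(path)
    if path.suffix == ".png":
        if spacing is None:
            raise ValueError(f"{path}: PNG masks need a spacing override")
        return read_mask_png(path, spacing)
    raise ValueError(f"unsupported mask format: {path.suffix!r}")


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
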