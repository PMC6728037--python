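"""Reading and writing frames, masks and manifests.

Frames come in as PNG/TIFF (spacing supplied by the caller, normally
from a manifest column or sidecar — never silently defaulted) or as
DICOM, where the spacing is read from the PixelSpacing /
ImagerPixelSpacing tags.  Phantom datasets are written as 8-bit PNG
frames plus PNG masks and a CSV manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .frames import UltrasoundFrame, as_spacing
from .phantom import PhantomPair

logger = logging.getLogger("bladdervol")


class MissingSpacingError(ValueError):
    """Raised when no physical pixel spacing can be determined."""


def _to_grayscale(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim == 3:
        logger.warning("RGB input %s converted to luma", path)
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if arr.dtype.kind in "ui":
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
        if arr.max() > 1.0:
            arr = arr / arr.max()
    return arr


def read_frame(path, section: str, spacing=None) -> UltrasoundFrame:
    """Read a grayscale frame from PNG/TIFF/DICOM.

    ``spacing`` (mm/px, scalar or (row, col)) is required for PNG/TIFF;
    for DICOM it is read from the pixel-spacing tags when not given.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom"}:
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        if spacing is None:
            tag = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
            if tag is None:
                raise MissingSpacingError(f"missing pixel spacing in DICOM {path}")
            spacing = (float(tag[0]), float(tag[1]))
    else:
        arr = iio.imread(path)
        if spacing is None:
            raise MissingSpacingError(f"missing pixel spacing for {path}")
    return UltrasoundFrame(image=_to_grayscale(np.asarray(arr), path), section=section, spacing=as_spacing(spacing))


def write_frame_png(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))


def write_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=np.uint8) * 255))


def write_dataset(pairs: List[PhantomPair], manifest: pd.DataFrame, outdir) -> pd.DataFrame:
    """Write a phantom dataset to disk and return the file manifest.

    Layout: ``<outdir>/<id>_{t,l}.png`` frames, ``<id>_{t,l}_mask.png``
    ground-truth masks, and ``manifest.csv`` with paths, spacing, true
    diameters and volumes (the schema the ``run`` pipeline consumes).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (_, meta), pair in zip(manifest.iterrows(), pairs):
        i = int(meta["id"])
        t_path, l_path = outdir / f"{i:04d}_t.png", outdir / f"{i:04d}_l.png"
        write_frame_png(t_path, pair.transverse_frame.image)
        write_frame_png(l_path, pair.longitudinal_frame.image)
        write_mask_png(outdir / f"{i:04d}_t_mask.png", pair.transverse_mask)
        write_mask_png(outdir / f"{i:04d}_l_mask.png", pair.longitudinal_mask)
        row = dict(meta)
        row.update(
            {
                "transverse_path": str(t_path),
                "longitudinal_path": str(l_path),
                "spacing_mm_per_px": pair.spec.pixel_spacing[0],
                "actual_volume_ml": pair.true_volume_ml,
            }
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "manifest.csv", index=False)
    return out
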