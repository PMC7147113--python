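"""File I/O: TIFF stacks, table CSVs, and run manifests.

Stacks are multi-page grayscale TIFFs, one page per z-slice with page 0 the
base slice; 16-bit on disk by default.  Tables travel as plain CSV with the
documented column schemas.  Calibration comes from the caller/config; any
conflicting embedded metadata loses, with a warning.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .scoring import Linescan
from .segmentation import ImageStack

__all__ = [
    "read_stack",
    "write_stack",
    "read_linescan_csv",
    "write_linescan_csv",
    "write_manifest",
    "file_sha256",
]

MEASUREMENT_COLUMNS = (
    "region_id", "condition", "actin_state", "trace_id",
    "path_length_um", "straightness", "base_area_um2", "n_nodes",
)
REGION_SUMMARY_COLUMNS = (
    "region_id", "condition", "actin_state", "fls_count",
    "mean_length_um", "mean_base_area_um2", "mean_straightness",
)
LINESCAN_COLUMNS = ("image_id", "filopodium_id", "role", "sample_index", "intensity")


def read_stack(
    path: str | Path,
    pixel_size_xy: float,
    z_step: float,
    region_id: str = "",
    condition: str = "",
    actin_state: str = "none_added",
) -> ImageStack:
    """Read a multi-page grayscale TIFF as a calibrated stack.

    Pages become z-slices in file order (page 0 = base slice); integer data
    is promoted to float64.  Calibration always comes from the arguments;
    embedded resolution metadata, if conflicting, is ignored with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            n_pages = len(tif.pages)
            if n_pages == 0:
                raise ValueError(f"TIFF has zero pages: {path}")
            if getattr(tif.pages[0], "samplesperpixel", 1) > 1:
                raise ValueError(
                    f"RGB/multichannel TIFF not supported (grayscale pages "
                    f"expected): {path}"
                )
            data = tif.asarray()
            _warn_on_conflicting_metadata(tif, pixel_size_xy, path)
    except (tifffile.TiffFileError, OSError) as err:
        raise ValueError(f"unreadable TIFF file {path}: {err}") from err
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(
            f"expected grayscale pages in {path}; got array of shape {data.shape} "
            "(RGB/multichannel input is not supported)"
        )
    return ImageStack(
        voxels=data.astype(float),
        pixel_size_xy=pixel_size_xy,
        z_step=z_step,
        region_id=region_id or path.stem,
        condition=condition,
        actin_state=actin_state,
    )


def _warn_on_conflicting_metadata(
    tif: "tifffile.TiffFile", pixel_size_xy: float, path: Path
) -> None:
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        if xres is None:
            return
        num, den = xres.value
        if num == 0 or (num, den) == (1, 1):  # writer default, not calibration
            return
        meta_px = den / num  # resolution is px per unit; invert to unit/px
        if not np.isclose(meta_px, pixel_size_xy, rtol=1e-3):
            warnings.warn(
                f"{path.name}: embedded pixel size {meta_px:g} conflicts with "
                f"configured {pixel_size_xy:g}; using the configured value",
                stacklevel=3,
            )
    except Exception:  # metadata probing is best-effort
        return


def write_stack(stack: ImageStack, path: str | Path, dtype: str = "uint16") -> Path:
    """Write a stack as a multi-page grayscale TIFF (16-bit by default)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.voxels
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(np.dtype(dtype))
        data = np.clip(np.round(data), info.min, info.max)
    data = data.astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def read_linescan_csv(path: str | Path) -> list[Linescan]:
    """Load linescans from long-format CSV (one row per intensity sample)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(LINESCAN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"linescan CSV missing columns: {sorted(missing)}")
    scans: list[Linescan] = []
    keys = ["image_id", "filopodium_id", "role"]
    df = df.copy()
    df["filopodium_id"] = df["filopodium_id"].fillna("")
    for (image_id, fid, role), grp in df.groupby(keys, sort=True, dropna=False):
        grp = grp.sort_values("sample_index")
        # Background scans carry a synthetic unique key in the CSV only.
        fid_out = None if str(role) == "background" else (str(fid) or None)
        scans.append(
            Linescan(
                intensities=tuple(float(v) for v in grp["intensity"]),
                role=str(role),
                image_id=str(image_id),
                filopodium_id=fid_out,
            )
        )
    return scans


def write_linescan_csv(scans: list[Linescan], path: str | Path) -> Path:
    """Write linescans to long-format CSV (round-trips read_linescan_csv)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan_idx, scan in enumerate(scans):
        for i, v in enumerate(scan.intensities):
            rows.append(
                {
                    "image_id": scan.image_id,
                    "filopodium_id": scan.filopodium_id
                    or f"bg{scan_idx:04d}",  # backgrounds need a unique key
                    "role": scan.role,
                    "sample_index": i,
                    "intensity": v,
                }
            )
    pd.DataFrame(rows, columns=list(LINESCAN_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"  # exact float round-trip
    )
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, **entries) -> Path:
    """Write a JSON run manifest (config, seed, input hashes, versions)."""
    import flsquant

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {"flsquant_version": flsquant.__version__, **entries}
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
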