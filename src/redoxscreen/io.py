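"""File interfaces: TIFF images, decay-cube stacks, IRF tables, manifests.

Conventions
-----------
* widefield channels: single-plane 16-bit grayscale TIFF;
* decay cubes: multi-page TIFF, one page per time-bin, plus a sidecar JSON
  ``<stem>.json`` with ``bin_width_ps`` and ``n_bins``;
* IRF: two-column CSV ``bin,counts`` (a single-row TIFF also reads);
* parameter maps: 32-bit float TIFF;
* manifests / tables: plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import IRF, DecayCube
from .errors import InterfaceError
from .flim import FlimFitResult
from .widefield import WidefieldPair


def write_image(path: str | Path, image: np.ndarray, dtype=np.uint16) -> Path:
    """Write a 2-D intensity image as grayscale TIFF (clipped to dtype range)."""
    path = Path(path)
    arr = np.asarray(image)
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        arr = np.clip(np.round(arr), info.min, info.max).astype(dtype)
    else:
        arr = arr.astype(dtype)
    tifffile.imwrite(path, arr)
    return path


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def read_pair(path_nadh: str | Path, path_fad: str | Path, metadata=None) -> WidefieldPair:
    return WidefieldPair(read_image(path_nadh), read_image(path_fad),
                         metadata=dict(metadata or {}))


def write_decay_cube(path: str | Path, cube: DecayCube) -> Path:
    """Multi-page TIFF (page k = time-bin k) + sidecar JSON with the time axis."""
    path = Path(path)
    pages = np.moveaxis(cube.counts.astype(np.uint32), 2, 0)
    tifffile.imwrite(path, pages)
    sidecar = {"bin_width_ps": cube.bin_width, "n_bins": cube.n_bins}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_decay_cube(path: str | Path) -> DecayCube:
    path = Path(path)
    pages = np.asarray(tifffile.imread(path))
    if pages.ndim != 3:
        raise InterfaceError(f"{path} is not a multi-page decay stack")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise InterfaceError(f"missing sidecar JSON {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    counts = np.moveaxis(pages, 0, 2)
    if counts.shape[2] != int(sidecar["n_bins"]):
        raise InterfaceError("sidecar n_bins does not match stack pages")
    return DecayCube(counts.astype(np.int64), float(sidecar["bin_width_ps"]))


def write_irf(path: str | Path, irf: IRF) -> Path:
    path = Path(path)
    df = pd.DataFrame({"bin": np.arange(irf.n_bins), "counts": irf.counts})
    df.to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps({"bin_width_ps": irf.bin_width}, indent=2))
    return path


def read_irf(path: str | Path, bin_width: float | None = None) -> IRF:
    """Read an IRF from 2-column CSV (or a single-row/column TIFF)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        counts = np.asarray(tifffile.imread(path), dtype=float).ravel()
    else:
        df = pd.read_csv(path)
        col = "counts" if "counts" in df.columns else df.columns[-1]
        counts = df[col].to_numpy(dtype=float)
    if bin_width is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            bin_width = float(json.loads(sidecar.read_text())["bin_width_ps"])
    kwargs = {} if bin_width is None else {"bin_width": bin_width}
    return IRF(counts, **kwargs)


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    return write_image(path, np.asarray(mask).astype(np.uint8) * 255, dtype=np.uint8)


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)) > 0


def write_fit_maps(out_dir: str | Path, result: FlimFitResult) -> list[Path]:
    """Per-parameter 32-bit float TIFF maps (NaN marks invalid pixels)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    maps = {"tau1": result.tau1, "tau2": result.tau2, "a1": result.a1,
            "a2": result.a2, "offset": result.offset, "chi2r": result.chi2r,
            "tau_m": result.tau_m,
            "photons": result.photons.astype(np.float32),
            "valid": result.valid.astype(np.float32)}
    for name, arr in maps.items():
        p = out / f"{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        written.append(p)
    return written


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
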