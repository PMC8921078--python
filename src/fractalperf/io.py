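"""Reading and writing NIfTI volumes, masks, FD maps, and sidecar metadata.

Series are stored as 4D NIfTI with axes (x, y, z, t) on disk and (t, z, y,
x) in memory; frame times, calibration state, and the noise estimate travel
in a JSON sidecar next to the volume. FD maps carry a sidecar recording the
scale set, kernel, connectivity, and calibration anchors, so any FD value
can be traced to its unit convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .preprocess import CAL_ENHANCED_ANCHOR, CAL_PRE_ANCHOR, DceSeries
from .fractal import FdMap


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dx, dy, dz, 1.0])


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_series(series: DceSeries, path: str | Path) -> Path:
    path = Path(path)
    vol = np.transpose(series.data, (3, 2, 1, 0))  # (t,z,y,x) -> (x,y,z,t)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), _affine(series.spacing)), str(path))
    meta = {
        "times_s": series.times.tolist(),
        "spacing_mm": list(series.spacing),
        "calibrated": series.calibrated,
        "sigma": series.sigma,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_series(path: str | Path) -> DceSeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.transpose(np.asarray(img.dataobj, dtype=float), (3, 2, 1, 0))
    meta = json.loads(_sidecar_path(path).read_text())
    return DceSeries(
        data=data,
        spacing=tuple(meta["spacing_mm"]),
        times=np.asarray(meta["times_s"], dtype=float),
        calibrated=bool(meta["calibrated"]),
        sigma=meta["sigma"],
    )


def write_mask(mask: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> Path:
    path = Path(path)
    vol = np.transpose(np.asarray(mask), (2, 1, 0)).astype(np.uint8)
    nib.save(nib.Nifti1Image(vol, _affine(spacing)), str(path))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.transpose(np.asarray(img.dataobj), (2, 1, 0)) > 0


def write_volume(vol_zyx: np.ndarray, spacing: tuple[float, float, float],
                 path: str | Path) -> Path:
    path = Path(path)
    vol = np.transpose(np.asarray(vol_zyx, dtype=np.float32), (2, 1, 0))
    nib.save(nib.Nifti1Image(vol, _affine(spacing)), str(path))
    return path


def read_volume(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.transpose(np.asarray(img.dataobj, dtype=float), (2, 1, 0))


def write_fd_map(fd_map: FdMap, spacing_yx: tuple[float, float], path: str | Path) -> Path:
    """FD map as a single-slice float NIfTI plus a JSON sidecar with the
    analysis convention."""
    path = Path(path)
    vol = np.transpose(fd_map.fd[None, :, :], (2, 1, 0)).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, _affine((1.0, *spacing_yx))), str(path))
    meta = {
        "scales": list(fd_map.scales),
        "kernel": fd_map.kernel,
        "timepoint": fd_map.timepoint,
        "calibration_anchors": [CAL_PRE_ANCHOR, CAL_ENHANCED_ANCHOR],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def write_phantom(phantom, outdir: str | Path) -> Path:
    """Write a phantom to a directory: series, masks, ADC, truth, spec."""
    import pandas as pd
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_series(phantom.series, outdir / "series.nii.gz")
    for name, mask in phantom.masks.items():
        write_mask(mask, phantom.series.spacing, outdir / f"mask_{name}.nii.gz")
    write_volume(phantom.adc, phantom.series.spacing, outdir / "adc.nii.gz")
    truth = {k: (list(v) if isinstance(v, tuple) else v) for k, v in phantom.truth.items()}
    pd.DataFrame([{k: json.dumps(v) if isinstance(v, list) else v for k, v in truth.items()}
                  ]).to_csv(outdir / "truth.csv", index=False)
    (outdir / "spec.yaml").write_text(yaml.safe_dump(phantom.spec.to_dict()))
    return outdir
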