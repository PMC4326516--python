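"""Reading and writing multi-echo stacks, T2 maps and contours.

Multi-echo data travel as 4-D NIfTI (echo along the 4th axis) with a
JSON sidecar holding echo times and noise metadata, or as a DICOM series
with one file per echo image (grouped by the EchoTime attribute).  T2
maps are written as float NIfTI in ms plus a JSON provenance record.
Contours are JSON lists of ``[x, y]`` pixel coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .fitting import MultiEchoStack, T2MapResult
from .noise import NoiseModel
from .segments import SegmentModel

__all__ = [
    "save_stack",
    "load_stack",
    "load_dicom_multiecho",
    "save_t2_map",
    "load_t2_map",
    "save_contours",
    "load_contours",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")


def save_stack(stack: MultiEchoStack, path) -> None:
    """Write a stack as 4-D NIfTI (x, y, 1, echo) + JSON sidecar."""
    path = Path(path)
    data = np.transpose(stack.volumes, (2, 1, 0))[:, :, None, :]  # (nx, ny, 1, ne)
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), path)
    meta = {"echo_times_ms": stack.echo_times.tolist()}
    if stack.noise is not None:
        meta["sigma"] = stack.noise.sigma
        meta["n_channels"] = stack.noise.n_channels
    if stack.protocol is not None:
        meta["protocol"] = stack.protocol.name
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_stack(path, protocol=None) -> MultiEchoStack:
    """Load a 4-D NIfTI multi-echo stack with its JSON sidecar."""
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI with echoes on the 4th axis")
    volumes = np.transpose(data[:, :, 0, :], (2, 1, 0))
    meta = json.loads(_sidecar(path).read_text())
    noise = None
    if "sigma" in meta:
        noise = NoiseModel(meta["sigma"], meta.get("n_channels", 1))
    return MultiEchoStack(
        volumes=volumes,
        echo_times=np.asarray(meta["echo_times_ms"], dtype=float),
        noise=noise,
        protocol=protocol,
    )


def load_dicom_multiecho(paths) -> MultiEchoStack:
    """Build a stack from single-frame DICOM files, one image per echo.

    ``paths`` is a directory or an iterable of files.  Images are grouped
    and ordered by their EchoTime attribute; all must share one matrix
    size.  Noise metadata is not carried by standard DICOM and must be
    estimated separately (e.g. :func:`grasemap.noise.estimate_sigma`).
    """
    p = Path(paths) if isinstance(paths, (str, Path)) else None
    files = sorted(p.iterdir()) if p is not None and p.is_dir() else [Path(f) for f in paths]
    by_te: dict[float, np.ndarray] = {}
    for f in files:
        ds = pydicom.dcmread(f)
        te = float(ds.EchoTime)
        if te in by_te:
            raise ValueError(f"duplicate EchoTime {te} ms in series")
        by_te[te] = ds.pixel_array.astype(float)
    if len(by_te) < 2:
        raise ValueError("need at least two echo images")
    tes = sorted(by_te)
    return MultiEchoStack(
        volumes=np.stack([by_te[t] for t in tes]),
        echo_times=np.asarray(tes, dtype=float),
    )


def save_t2_map(result: T2MapResult, path) -> None:
    """Write the T2 map (ms) as NIfTI plus a JSON provenance sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(result.t2_map.T.astype(np.float32), affine=np.eye(4)), path)
    meta = dict(result.meta)
    meta["method"] = result.method
    meta["n_converged"] = int(result.converged_mask.sum())
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_t2_map(path) -> tuple[np.ndarray, dict]:
    """Load a T2 map written by :func:`save_t2_map`; returns (map, meta)."""
    path = Path(path)
    img = nib.load(path)
    t2 = np.asarray(img.dataobj, dtype=float).T
    meta = json.loads(_sidecar(path).read_text())
    return t2, meta


def save_contours(model: SegmentModel, path) -> None:
    """Write a SegmentModel as a JSON contour file."""
    payload = {
        "endo": model.endo_contour.tolist(),
        "epi": model.epi_contour.tolist(),
        "rv_insertion": model.rv_insertion.tolist(),
        "slice_level": model.slice_level,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_contours(path) -> SegmentModel:
    """Read a JSON contour file into a SegmentModel."""
    d = json.loads(Path(path).read_text())
    return SegmentModel(
        endo_contour=np.asarray(d["endo"], dtype=float),
        epi_contour=np.asarray(d["epi"], dtype=float),
        rv_insertion=np.asarray(d["rv_insertion"], dtype=float),
        slice_level=d["slice_level"],
    )
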