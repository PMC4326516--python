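"""AHA 16-segment geometry and per-segment / global T2 statistics.

The left ventricle is partitioned into 16 standardized segments: six
basal, six mid-ventricular and four apical, defined on short-axis slices
by angular sectors about the cavity centre, anchored at the anterior
right-ventricular (RV) insertion point.

Angular convention used throughout (recorded in report metadata):
display angle ``phi = atan2(y_c - y, x - x_c)`` (anterior up, septum
image-left, angles increase counterclockwise in the displayed image);
sectors proceed from the RV-insertion ray *through the septum*.  Basal
and mid slices use six 60-degree sectors in the order anterior,
anteroseptal, inferoseptal, inferior, inferolateral, anterolateral;
apical slices use four 90-degree sectors (anterior, septal, inferior,
lateral) with the septal sector centred on the septum, i.e. 120 degrees
past the RV ray.  At a sector boundary the lower AHA index wins (each
boundary belongs to the sector it starts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as _PolyPath

__all__ = [
    "SegmentModel",
    "SegmentReport",
    "SEGMENT_NAMES",
    "segment_ids",
    "assign_segments",
    "segment_report",
    "regional_contrasts",
]

_BASAL_MID_ORDER = [
    "anterior",
    "anteroseptal",
    "inferoseptal",
    "inferior",
    "inferolateral",
    "anterolateral",
]
_APICAL_ORDER = ["anterior", "septal", "inferior", "lateral"]

#: AHA segment id -> (slice level, wall name); ids 1-6 basal, 7-12 mid, 13-16 apical
SEGMENT_NAMES: dict[int, tuple[str, str]] = {
    **{i + 1: ("basal", n) for i, n in enumerate(_BASAL_MID_ORDER)},
    **{i + 7: ("mid", n) for i, n in enumerate(_BASAL_MID_ORDER)},
    **{i + 13: ("apical", n) for i, n in enumerate(_APICAL_ORDER)},
}

_LEVEL_OFFSET = {"basal": 0, "mid": 6, "apical": 12}


def segment_ids(slice_level: str) -> list[int]:
    """AHA segment ids belonging to one short-axis slice level."""
    if slice_level not in _LEVEL_OFFSET:
        raise ValueError("slice_level must be 'basal', 'mid' or 'apical'")
    off = _LEVEL_OFFSET[slice_level]
    n = 4 if slice_level == "apical" else 6
    return list(range(off + 1, off + 1 + n))


@dataclass
class SegmentModel:
    """Myocardial contours plus the anatomical landmarks fixing segments.

    ``endo_contour`` and ``epi_contour`` are closed polygons as ``(N, 2)``
    arrays of ``[x, y]`` pixel coordinates (0-based, pixel centres at
    integer coordinates); ``rv_insertion`` is the anterior RV insertion
    point ``[x, y]``.
    """

    endo_contour: np.ndarray
    epi_contour: np.ndarray
    rv_insertion: np.ndarray
    slice_level: str

    def __post_init__(self) -> None:
        self.endo_contour = np.asarray(self.endo_contour, dtype=float)
        self.epi_contour = np.asarray(self.epi_contour, dtype=float)
        self.rv_insertion = np.asarray(self.rv_insertion, dtype=float)
        for c in (self.endo_contour, self.epi_contour):
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
                raise ValueError("contours must be (N>=3, 2) arrays of [x, y]")
        if self.rv_insertion.shape != (2,):
            raise ValueError("rv_insertion must be a single [x, y] point")
        if self.slice_level not in _LEVEL_OFFSET:
            raise ValueError("slice_level must be 'basal', 'mid' or 'apical'")
        if _PolyPath(self.endo_contour).contains_point(self.rv_insertion):
            raise ValueError("rv_insertion must lie outside the endocardial contour")

    @property
    def n_segments(self) -> int:
        return 4 if self.slice_level == "apical" else 6


def _display_angle(x, y, xc: float, yc: float):
    """Angle in degrees, anterior (display-up) = 90, image-left = 180."""
    return np.degrees(np.arctan2(yc - np.asarray(y), np.asarray(x) - xc)) % 360.0


def assign_segments(model: SegmentModel, image_shape: tuple[int, int]) -> np.ndarray:
    """Label every myocardial pixel with its AHA segment id.

    Myocardial pixels are those whose centre lies inside the epicardial
    and outside the endocardial polygon.  Angles are measured about the
    centroid of the endocardial contour; see the module docstring for the
    sector convention.  Returns an integer label map (0 = not myocardium,
    otherwise the AHA id 1-16).
    """
    ny, nx = image_shape
    endo = _PolyPath(model.endo_contour)
    epi = _PolyPath(model.epi_contour)
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    myo = epi.contains_points(pts) & ~endo.contains_points(pts)
    if not np.any(myo):
        raise ValueError("degenerate contours: no myocardial pixels")

    xc, yc = model.endo_contour.mean(axis=0)
    phi = _display_angle(pts[:, 0], pts[:, 1], xc, yc)
    phi_rv = _display_angle(model.rv_insertion[0], model.rv_insertion[1], xc, yc)

    if model.slice_level == "apical":
        # septal sector centred 120 deg past the RV ray (mid-septum):
        # sectors start 15 deg before the RV ray
        rel = (phi - (phi_rv - 15.0)) % 360.0
        sector = np.floor(rel / 90.0).astype(int)
    else:
        rel = (phi - phi_rv) % 360.0
        sector = np.floor(rel / 60.0).astype(int)
    labels = np.zeros(pts.shape[0], dtype=int)
    labels[myo] = sector[myo] + _LEVEL_OFFSET[model.slice_level] + 1
    return labels.reshape(ny, nx)


@dataclass
class SegmentReport:
    """Per-segment and global T2 statistics for one short-axis slice.

    ``table`` has one row per segment (aha_id, level, name, mean_ms,
    sd_ms, n_pixels).  ``global_mean`` is the unweighted mean of segment
    means and ``global_sd`` the population standard deviation (divide by
    n) of the segment means; a pixel-weighted alternative over all
    myocardial pixels is kept alongside.  The aggregation rule is
    recorded in ``meta``.
    """

    table: pd.DataFrame
    global_mean: float
    global_sd: float
    global_mean_pixelweighted: float
    global_sd_pixelweighted: float
    meta: dict

    @property
    def segment_means(self) -> pd.Series:
        return self.table.set_index("aha_id")["mean_ms"]


def segment_report(t2_map, labels: np.ndarray, converged: np.ndarray | None = None) -> SegmentReport:
    """Per-segment mean/SD and the global summary of a T2 map.

    ``t2_map`` may be a :class:`grasemap.fitting.T2MapResult` (its
    convergence mask is then honoured) or a plain array.  Empty segments
    (no valid pixel) are excluded from the global aggregation and listed
    in ``meta["empty_segments"]``.
    """
    from .fitting import T2MapResult

    if isinstance(t2_map, T2MapResult):
        values = t2_map.t2_map
        converged = t2_map.converged_mask if converged is None else converged
    else:
        values = np.asarray(t2_map, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != values.shape:
        raise ValueError("label map and T2 map shapes differ")
    valid = np.ones(values.shape, dtype=bool) if converged is None else np.asarray(converged, dtype=bool)

    rows, empty = [], []
    for sid in sorted(np.unique(labels[labels > 0])):
        sel = (labels == sid) & valid
        level, name = SEGMENT_NAMES[int(sid)]
        if not np.any(sel):
            empty.append(int(sid))
            continue
        vals = values[sel]
        rows.append(
            {
                "aha_id": int(sid),
                "level": level,
                "name": name,
                "mean_ms": float(vals.mean()),
                "sd_ms": float(vals.std(ddof=0)),
                "n_pixels": int(vals.size),
            }
        )
    if not rows:
        raise ValueError("no segment contains a valid pixel")
    table = pd.DataFrame(rows)
    seg_means = table["mean_ms"].to_numpy()
    pix = valid & (labels > 0)
    meta = {
        "global_rule": "unweighted mean of segment means; population SD of segment means",
        "angular_convention": "counterclockwise in display from the RV-insertion ray, through the septum",
        "empty_segments": empty,
    }
    return SegmentReport(
        table=table,
        global_mean=float(seg_means.mean()),
        global_sd=float(seg_means.std(ddof=0)),
        global_mean_pixelweighted=float(values[pix].mean()),
        global_sd_pixelweighted=float(values[pix].std(ddof=0)),
        meta=meta,
    )


def regional_contrasts(reports: dict[str, SegmentReport]) -> dict:
    """Slice-level and wall-level mean T2 differences.

    ``reports`` maps slice level (``"basal"|"mid"|"apical"``) to its
    :class:`SegmentReport`.  Returns slice means, the pairwise slice
    differences (apical - mid, apical - basal, mid - basal) and the
    septal-vs-lateral wall contrast pooled over the available slices.
    Missing slices are flagged and their contrasts set to None.
    """
    out: dict = {"missing_slices": [lv for lv in ("basal", "mid", "apical") if lv not in reports]}
    slice_means = {lv: rep.global_mean for lv, rep in reports.items()}
    out["slice_means"] = slice_means

    def diff(a: str, b: str):
        if a in slice_means and b in slice_means:
            return slice_means[a] - slice_means[b]
        return None

    out["apical_minus_mid"] = diff("apical", "mid")
    out["apical_minus_basal"] = diff("apical", "basal")
    out["mid_minus_basal"] = diff("mid", "basal")

    septal, lateral = [], []
    for rep in reports.values():
        t = rep.table
        septal.extend(t.loc[t["name"].str.contains("septal"), "mean_ms"])
        lateral.extend(t.loc[t["name"].str.contains("lateral"), "mean_ms"])
    out["septal_minus_lateral"] = (
        float(np.mean(septal) - np.mean(lateral)) if septal and lateral else None
    )
    return out
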