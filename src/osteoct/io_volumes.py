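"""Volume, mask, ROI, and report I/O with explicit voxel-spacing metadata.

Micro-CT stacks are handled as 8-bit grayscale volumes with isotropic voxel
spacing given in micrometres.  Plain TIFF does not store physical spacing
reliably, so every volume written by this package gets a JSON sidecar
(``<file>.meta.json`` with key ``spacing_um``); a spacing passed at call time
always overrides the sidecar.

Axis convention: arrays are indexed ``(z, y, x)`` with 0-based, voxel-centered
coordinates; ``z`` increases distally (articular surface at low ``z``, growth
plate at high ``z``).  ROI polygons use 0-based pixel coordinates of vertex
centers; rasterization includes voxels whose centers are inside or on the
polygon boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

SIDECAR_SUFFIX = ".meta.json"

COMPARTMENTS = ("medial", "lateral")

#: Canonical column order for morphometry reports (Table-style layout).
REPORT_COLUMNS = [
    "animal",
    "limb",
    "week",
    "compartment",
    "bv_mm3",
    "tv_mm3",
    "bvtv_pct",
    "tbth_um",
    "tbsp_um",
    "tbn_per_mm",
    "plth_um",
    "plpor_pct",
    "pct_diff",
]

#: Rounding used by the companion "table view" of a report: integers for
#: length (μm) and volume (mm³) columns, one decimal for percentages, Tb.N,
#: and percent differences.
_ROUND_RULES = {
    "bv_mm3": 0,
    "tv_mm3": 0,
    "bvtv_pct": 1,
    "tbth_um": 0,
    "tbsp_um": 0,
    "tbn_per_mm": 1,
    "plth_um": 0,
    "plpor_pct": 1,
    "pct_diff": 1,
}


class VolumeFormatError(ValueError):
    """Raised for unreadable or inconsistent volume data."""


@dataclass
class GrayVolume:
    """An 8-bit grayscale image stack with isotropic voxel spacing (μm)."""

    voxels: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D stack, got ndim={self.voxels.ndim}"
            )
        if self.voxels.dtype != np.uint8:
            raise VolumeFormatError(
                f"expected 8-bit (uint8) intensities, got {self.voxels.dtype}"
            )
        if min(self.voxels.shape) < 1:
            raise VolumeFormatError("all three dimensions must be >= 1")
        if not (self.spacing > 0):
            raise ValueError(f"spacing must be > 0 μm, got {self.spacing}")
        self.spacing = float(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class BinaryVolume:
    """A bone/background mask; ``threshold`` records its segmentation provenance."""

    voxels: np.ndarray
    spacing: float
    threshold: int | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D mask, got ndim={self.voxels.ndim}"
            )
        if self.voxels.dtype != bool:
            vals = np.unique(self.voxels)
            if not np.isin(vals, (0, 1, 255)).all():
                raise VolumeFormatError(
                    "mask values must be boolean or {0, 255}"
                )
            self.voxels = self.voxels != 0
        if not (self.spacing > 0):
            raise ValueError(f"spacing must be > 0 μm, got {self.spacing}")
        self.spacing = float(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class RoiSlice:
    """One closed polygon on one slice, labeled with its compartment."""

    slice_index: int
    compartment: str
    vertices: np.ndarray  # (n, 2) array of (x, y) pixel coordinates

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {COMPARTMENTS}, got "
                f"{self.compartment!r}"
            )
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class RoiStack:
    """Stacked per-slice polygon ROIs for the medial and lateral compartments.

    Invariants enforced at construction: polygons are simple, per-compartment
    slice indices strictly increase, and on any given slice the medial and
    lateral polygons do not overlap (interiors disjoint).
    """

    slices: list[RoiSlice] = field(default_factory=list)

    def __post_init__(self) -> None:
        per_comp: dict[str, list[int]] = {c: [] for c in COMPARTMENTS}
        per_slice: dict[int, dict[str, Polygon]] = {}
        for s in self.slices:
            poly = s.polygon()
            if not poly.is_valid or poly.area <= 0:
                raise ValueError(
                    f"polygon on slice {s.slice_index} ({s.compartment}) is "
                    "not a simple closed polygon"
                )
            per_comp[s.compartment].append(s.slice_index)
            per_slice.setdefault(s.slice_index, {})[s.compartment] = poly
        for comp, idx in per_comp.items():
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(
                    f"{comp} slice indices must be strictly increasing"
                )
        for k, polys in per_slice.items():
            if len(polys) == 2:
                inter = polys["medial"].intersection(polys["lateral"])
                if inter.area > 1e-9:
                    raise ValueError(
                        f"medial and lateral polygons overlap on slice {k}"
                    )

    @property
    def n_slices(self) -> int:
        return len({s.slice_index for s in self.slices})

    def slice_indices(self) -> list[int]:
        return sorted({s.slice_index for s in self.slices})


# ---------------------------------------------------------------------------
# spacing sidecars


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + SIDECAR_SUFFIX)


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists() and path.is_dir():
        sc = path / ("meta" + SIDECAR_SUFFIX)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def _write_sidecar(path: Path, meta: Mapping) -> None:
    _sidecar_path(path).write_text(json.dumps(dict(meta), indent=1))


def _resolve_spacing(path: Path, spacing: float | None) -> float:
    if spacing is not None:
        return float(spacing)
    meta = _read_sidecar(path)
    if "spacing_um" in meta:
        return float(meta["spacing_um"])
    raise VolumeFormatError(
        f"no voxel spacing given and no sidecar found for {path}"
    )


# ---------------------------------------------------------------------------
# volumes


def read_volume(path: str | Path, spacing: float | None = None) -> GrayVolume:
    """Read a multi-page TIFF or a directory of equally-sized 2D slices.

    Slices are stacked in page order (multi-page TIFF) or sorted filename
    order (directory).  ``spacing`` (μm) overrides the sidecar metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".tif", ".tiff", ".png"}
        )
        if not files:
            raise VolumeFormatError(f"no slice images found in {path}")
        slices = [tifffile.imread(f) if f.suffix.lower() != ".png"
                  else _read_png(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise VolumeFormatError(
                f"inconsistent slice dimensions in {path}: {sorted(shapes)}"
            )
        arr = np.stack(slices, axis=0)
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None, :, :]
    if arr.dtype != np.uint8:
        raise VolumeFormatError(
            f"unsupported format: expected 8-bit data, got {arr.dtype}"
        )
    return GrayVolume(arr, _resolve_spacing(path, spacing))


def _read_png(path: Path) -> np.ndarray:
    from imageio.v3 import imread  # optional dialect; tifffile covers TIFF

    a = imread(path)
    if a.ndim == 3:  # collapse grayscale-stored-as-RGB
        a = a[..., 0]
    return a


def write_volume(vol: GrayVolume, path: str | Path) -> Path:
    """Write a multi-page 8-bit TIFF plus its spacing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, vol.voxels)
    _write_sidecar(path, {"spacing_um": vol.spacing})
    return path


def read_mask(path: str | Path, spacing: float | None = None) -> BinaryVolume:
    """Read a {0, 255} 8-bit TIFF mask; threshold provenance from the sidecar."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    meta = _read_sidecar(path)
    thr = meta.get("threshold")
    return BinaryVolume(arr != 0, _resolve_spacing(path, spacing),
                        None if thr is None else int(thr))


def write_mask(mask: BinaryVolume, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, (mask.voxels.astype(np.uint8) * 255))
    meta = {"spacing_um": mask.spacing}
    if mask.threshold is not None:
        meta["threshold"] = int(mask.threshold)
    _write_sidecar(path, meta)
    return path


# ---------------------------------------------------------------------------
# ROI files


def read_roi_stack(path: str | Path) -> RoiStack:
    """Read ROI polygons from JSON: a list of {slice, compartment, vertices}."""
    entries = json.loads(Path(path).read_text())
    return RoiStack([
        RoiSlice(int(e["slice"]), str(e["compartment"]),
                 np.asarray(e["vertices"], dtype=float))
        for e in entries
    ])


def write_roi_stack(rois: RoiStack, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([
        {
            "slice": s.slice_index,
            "compartment": s.compartment,
            "vertices": s.vertices.tolist(),
        }
        for s in rois.slices
    ], indent=1))
    return path


# ---------------------------------------------------------------------------
# reports


def _as_dataframe(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for r in records:
        if isinstance(r, Mapping):
            rows.append(dict(r))
        else:  # dataclass-like
            rows.append({k: v for k, v in vars(r).items()})
    return pd.DataFrame(rows)


def write_report(records, path: str | Path) -> tuple[Path, Path]:
    """Write a morphometry report as CSV, with a companion rounded view.

    ``records`` is a DataFrame or an iterable of mappings/dataclasses, one
    row per animal-limb-timepoint-compartment.  The main CSV keeps full
    precision; ``<stem>.table.csv`` applies the published rounding (integers
    for μm/mm³ columns, one decimal for %, Tb.N, and %d).  Column order is
    deterministic: canonical report columns first, extras sorted.
    """
    df = _as_dataframe(records)
    if df.empty:
        raise ValueError("cannot write an empty report")
    cols = [c for c in REPORT_COLUMNS if c in df.columns]
    cols += sorted(c for c in df.columns if c not in cols)
    df = df[cols]
    path = Path(path)
    df.to_csv(path, index=False)
    rounded = df.copy()
    for c, nd in _ROUND_RULES.items():
        if c in rounded.columns:
            r = pd.to_numeric(rounded[c], errors="coerce").round(nd)
            rounded[c] = r.astype("Int64") if nd == 0 else r
    table_path = path.with_suffix(".table.csv")
    rounded.to_csv(table_path, index=False)
    return path, table_path
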