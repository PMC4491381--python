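"""Core data containers, polygon geometry, rasterization, and file I/O.

Conventions used throughout the package
---------------------------------------
* Image arrays are indexed ``(slice, frame, row, col)``. Slice index 0 is
  the most basal slice, the last index the most apical.
* Contour nodes live in continuous pixel coordinates ``(x, y)`` with
  ``x = column`` and ``y = row``, 0-based, origin at the center of the
  top-left pixel.
* Closed contours are stored as an ordered open chain of nodes (the last
  node connects back to the first implicitly) with counter-clockwise
  orientation, defined as positive shoelace area in (x, y).
* Metric thresholds (mm) are always converted through the pixel spacing
  before being applied in pixel space.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass

import numpy as np
import nibabel as nib

from .errors import DegenerateContourError, MetadataError, SchemaVersionError

CONTOUR_SCHEMA_VERSION = 1
N_SECTORS = 24
DEFAULT_NODE_COUNT = 80


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CineStack:
    """A 4D short-axis cine stack plus the geometry needed for metric output.

    Parameters
    ----------
    intensities
        Scalar array indexed ``(slice, frame, row, col)``; finite and
        non-negative.
    pixel_spacing_mm
        In-plane spacing ``(row, col)`` in mm, both strictly positive.
    slice_spacing_mm
        Center-to-center slice distance (thickness + gap) in mm.
    frame_duration_ms
        Duration of one reconstructed time frame in ms.
    heart_rate_bpm
        Heart rate; with retrospective gating one cycle spans all frames.
    analyzed_slice_range
        Inclusive ``(basal_idx, apical_idx)`` of slices containing any
        myocardium — the only user input the segmentation method needs.
    """

    intensities: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_spacing_mm: float
    frame_duration_ms: float
    heart_rate_bpm: float
    analyzed_slice_range: tuple[int, int] | None = None

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 4:
            raise MetadataError(
                f"intensities must be 4D (slice, frame, row, col); got {arr.ndim}D"
            )
        if not np.all(np.isfinite(arr)):
            raise MetadataError("intensities contain non-finite values")
        if arr.min() < 0:
            raise MetadataError("intensities must be non-negative")
        self.intensities = arr
        sr, sc = self.pixel_spacing_mm
        for name, v in (
            ("pixel_spacing_mm[row]", sr),
            ("pixel_spacing_mm[col]", sc),
            ("slice_spacing_mm", self.slice_spacing_mm),
            ("frame_duration_ms", self.frame_duration_ms),
            ("heart_rate_bpm", self.heart_rate_bpm),
        ):
            if not (np.isfinite(v) and v > 0):
                raise MetadataError(f"{name} must be strictly positive; got {v!r}")
        if self.analyzed_slice_range is None:
            self.analyzed_slice_range = (0, arr.shape[0] - 1)
        b, a = self.analyzed_slice_range
        if not (0 <= b <= a < arr.shape[0]):
            raise MetadataError(
                f"analyzed_slice_range {self.analyzed_slice_range} outside "
                f"slice bounds [0, {arr.shape[0] - 1}]"
            )
        self.analyzed_slice_range = (int(b), int(a))

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.intensities.shape[2:]

    @property
    def analyzed_slices(self) -> range:
        b, a = self.analyzed_slice_range
        return range(b, a + 1)

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1])


@dataclass
class Contour:
    """A closed planar node chain for one border in one slice/frame."""

    nodes: np.ndarray  # (N, 2) float, (x, y) pixel coordinates
    slice_idx: int = 0
    frame_idx: int = 0
    border: str = "endo"  # "endo" | "epi"

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=np.float64)
        if nodes.ndim != 2 or nodes.shape[1] != 2:
            raise DegenerateContourError(f"nodes must be (N, 2); got {nodes.shape}")
        if nodes.shape[0] < 8:
            raise DegenerateContourError(
                f"contour needs >= 8 nodes; got {nodes.shape[0]}"
            )
        if not np.all(np.isfinite(nodes)):
            raise DegenerateContourError("contour nodes contain non-finite values")
        if self.border not in ("endo", "epi"):
            raise ValueError(f"border must be 'endo' or 'epi'; got {self.border!r}")
        self.nodes = ensure_ccw(nodes)

    @property
    def area(self) -> float:
        return abs(polygon_area(self.nodes))


@dataclass
class SegmentationResult:
    """Paired endo/epi contour sets with outflow flags and long-axis motion.

    ``endo_nodes``/``epi_nodes`` are ``(S, F, N, 2)`` arrays over the
    analyzed slices (S) and all frames (F); ``present`` marks slice/frames
    that still carry a contour (basal slice/frames fully removed by the
    long-axis motion correction are absent). ``outflow_flags`` is
    ``(S, F, 24)`` boolean; ``longaxis_displacement`` counts, per frame, the
    basal slices removed relative to end-diastole.
    """

    endo_nodes: np.ndarray
    epi_nodes: np.ndarray
    present: np.ndarray
    outflow_flags: np.ndarray
    longaxis_displacement: np.ndarray
    slice_offset: int = 0  # absolute index of the first analyzed slice
    ed_frame: int | None = None
    es_frame: int | None = None

    def __post_init__(self):
        self.endo_nodes = np.asarray(self.endo_nodes, dtype=np.float64)
        self.epi_nodes = np.asarray(self.epi_nodes, dtype=np.float64)
        self.present = np.asarray(self.present, dtype=bool)
        self.outflow_flags = np.asarray(self.outflow_flags, dtype=bool)
        self.longaxis_displacement = np.asarray(
            self.longaxis_displacement, dtype=np.int64
        )
        if self.endo_nodes.shape != self.epi_nodes.shape:
            raise ValueError("endo and epi node arrays must share a shape")
        s, f = self.endo_nodes.shape[:2]
        if self.present.shape != (s, f):
            raise ValueError("present mask shape mismatch")
        if self.outflow_flags.shape != (s, f, N_SECTORS):
            raise ValueError(f"outflow_flags must be (S, F, {N_SECTORS})")
        if self.longaxis_displacement.shape != (f,):
            raise ValueError("longaxis_displacement must be per-frame")

    @property
    def n_slices(self) -> int:
        return self.endo_nodes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.endo_nodes.shape[1]

    def contour(self, slice_idx: int, frame_idx: int, border: str) -> Contour | None:
        """Contour at an *analyzed-range-relative* slice index, or None."""
        if not self.present[slice_idx, frame_idx]:
            return None
        nodes = self.endo_nodes if border == "endo" else self.epi_nodes
        return Contour(
            nodes[slice_idx, frame_idx],
            slice_idx=slice_idx + self.slice_offset,
            frame_idx=frame_idx,
            border=border,
        )


# ---------------------------------------------------------------------------
# Polygon geometry
# ---------------------------------------------------------------------------

def polygon_area(nodes: np.ndarray) -> float:
    """Signed shoelace area; positive for counter-clockwise chains."""
    x = nodes[..., 0]
    y = nodes[..., 1]
    return float(
        0.5 * np.sum(x * np.roll(y, -1, axis=-1) - np.roll(x, -1, axis=-1) * y, axis=-1)
    )


def signed_areas(nodes: np.ndarray) -> np.ndarray:
    """Batched signed shoelace area for (..., N, 2) node arrays."""
    x = nodes[..., 0]
    y = nodes[..., 1]
    return 0.5 * np.sum(
        x * np.roll(y, -1, axis=-1) - np.roll(x, -1, axis=-1) * y, axis=-1
    )


def ensure_ccw(nodes: np.ndarray) -> np.ndarray:
    """Return the chain in counter-clockwise orientation (idempotent)."""
    if polygon_area(nodes) < 0:
        return nodes[::-1].copy()
    return np.asarray(nodes, dtype=np.float64)


def outward_normals(nodes: np.ndarray) -> np.ndarray:
    """Unit outward normals for CCW (..., N, 2) closed chains.

    The tangent is the centered difference along the chain; for the CCW
    orientation used here the outward normal is the tangent rotated by
    -90 degrees, i.e. ``(t_y, -t_x)``.
    """
    t = np.roll(nodes, -1, axis=-2) - np.roll(nodes, 1, axis=-2)
    n = np.stack([t[..., 1], -t[..., 0]], axis=-1)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    return n / np.maximum(norm, 1e-12)


def resample_closed(nodes: np.ndarray, n_out: int | None = None) -> np.ndarray:
    """Resample closed chains to equal arc-length node spacing.

    Works on batched ``(..., N, 2)`` arrays; preserves the polygonal curve
    (new nodes are placed on the existing segments) and keeps node 0 at the
    start of the original chain.
    """
    nodes = np.asarray(nodes, dtype=np.float64)
    n_in = nodes.shape[-2]
    if n_out is None:
        n_out = n_in
    closed = np.concatenate([nodes, nodes[..., :1, :]], axis=-2)  # (..., N+1, 2)
    seg = np.linalg.norm(np.diff(closed, axis=-2), axis=-1)  # (..., N)
    cum = np.concatenate(
        [np.zeros(seg.shape[:-1] + (1,)), np.cumsum(seg, axis=-1)], axis=-1
    )  # (..., N+1)
    total = cum[..., -1:]
    if np.any(total <= 1e-12):
        raise DegenerateContourError("zero-length contour cannot be resampled")
    t = (np.arange(n_out) / n_out) * total  # (..., n_out)
    # segment index for each target arc length (vectorized searchsorted)
    idx = np.sum(t[..., :, None] >= cum[..., None, :-1], axis=-1) - 1
    idx = np.clip(idx, 0, n_in - 1)
    seg_len = np.take_along_axis(seg, idx, axis=-1)
    seg_start = np.take_along_axis(cum[..., :-1], idx, axis=-1)
    frac = (t - seg_start) / np.maximum(seg_len, 1e-12)
    frac = np.clip(frac, 0.0, 1.0)
    p0 = np.take_along_axis(closed, idx[..., None], axis=-2)
    p1 = np.take_along_axis(closed, (idx + 1)[..., None], axis=-2)
    return p0 + frac[..., None] * (p1 - p0)


def anchor_start(nodes: np.ndarray) -> np.ndarray:
    """Roll each chain so node 0 is the node closest to the +x direction
    from the chain centroid. Keeps node identity roughly consistent across
    slices and frames, which the inter-slice/temporal coupling relies on."""
    nodes = np.asarray(nodes, dtype=np.float64)
    centroid = nodes.mean(axis=-2, keepdims=True)
    rel = nodes - centroid
    ang = np.arctan2(rel[..., 1], rel[..., 0])
    k = np.argmin(np.abs(np.angle(np.exp(1j * ang))), axis=-1)  # (...,)
    n = nodes.shape[-2]
    shift = (k[..., None] + np.arange(n)) % n
    return np.take_along_axis(nodes, shift[..., None], axis=-2)


def rasterize(contour: Contour | np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of pixels whose centers lie inside a closed polygon.

    Even-odd (crossing-number) rule on pixel centers; deterministic. Raises
    for degenerate polygons with area below one pixel.
    """
    nodes = contour.nodes if isinstance(contour, Contour) else np.asarray(contour)
    nodes = np.asarray(nodes, dtype=np.float64)
    if abs(polygon_area(nodes)) < 1.0:
        raise DegenerateContourError(
            f"polygon area {abs(polygon_area(nodes)):.3g} px^2 is below 1 pixel"
        )
    rows, cols = grid_shape
    mask = np.zeros((rows, cols), dtype=bool)
    # restrict to the bounding box for speed
    r0 = max(int(np.floor(nodes[:, 1].min())), 0)
    r1 = min(int(np.ceil(nodes[:, 1].max())) + 1, rows)
    c0 = max(int(np.floor(nodes[:, 0].min())), 0)
    c1 = min(int(np.ceil(nodes[:, 0].max())) + 1, cols)
    if r0 >= r1 or c0 >= c1:
        return mask
    yc = np.arange(r0, r1, dtype=np.float64)[:, None]  # (R, 1)
    xc = np.arange(c0, c1, dtype=np.float64)[None, :]  # (1, C)
    x1, y1 = nodes[:, 0], nodes[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    inside = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    for e in range(nodes.shape[0]):
        crosses = (y1[e] > yc) != (y2[e] > yc)  # (R, 1)
        if not crosses.any():
            continue
        x_int = x1[e] + (yc - y1[e]) * (x2[e] - x1[e]) / (y2[e] - y1[e])
        inside ^= crosses & (xc < x_int)
    mask[r0:r1, c0:c1] = inside
    return mask


# ---------------------------------------------------------------------------
# Stack I/O: NIfTI-1 and the native .lvz archive
# ---------------------------------------------------------------------------

def write_stack(stack: CineStack, path) -> None:
    """Write a stack to NIfTI-1 (``.nii``/``.nii.gz``) or the native
    ``.lvz`` archive (a zip holding the 4D array and a JSON metadata block).

    NIfTI stores dims as (x, y, slice, frame); the heart rate is recovered
    on read from the cycle length (frames x frame duration). The archive
    format round-trips every metadata field exactly.
    """
    path = str(path)
    if path.endswith(".lvz"):
        _write_archive(stack, path)
        return
    sr, sc = stack.pixel_spacing_mm
    data = stack.intensities.transpose(3, 2, 0, 1)  # (x=col, y=row, z, t)
    affine = np.diag([sc, sr, stack.slice_spacing_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms((sc, sr, stack.slice_spacing_mm, stack.frame_duration_ms))
    img.header.set_xyzt_units("mm", "msec")
    nib.save(img, path)


def read_stack(path, analyzed_slice_range=None) -> CineStack:
    """Read a stack from NIfTI-1 or the native ``.lvz`` archive."""
    path = str(path)
    if path.endswith(".lvz"):
        return _read_archive(path, analyzed_slice_range)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise MetadataError(
            f"expected a 4D cine volume, got {data.ndim}D data in {path}"
        )
    zooms = img.header.get_zooms()
    if len(zooms) < 4:
        raise MetadataError("missing field: frame_duration (4th pixdim)")
    sc, sr, sz, dt = (float(z) for z in zooms[:4])
    if sc <= 0 or sr <= 0:
        raise MetadataError("missing field: pixel_spacing (zero pixdim)")
    if sz <= 0:
        raise MetadataError("missing field: slice_spacing (zero pixdim)")
    if dt <= 0:
        raise MetadataError("missing field: frame_duration (zero pixdim)")
    n_frames = data.shape[3]
    heart_rate = 60000.0 / (dt * n_frames)
    return CineStack(
        intensities=data.transpose(2, 3, 1, 0).astype(np.float64),
        pixel_spacing_mm=(sr, sc),
        slice_spacing_mm=sz,
        frame_duration_ms=dt,
        heart_rate_bpm=heart_rate,
        analyzed_slice_range=analyzed_slice_range,
    )


def _write_archive(stack: CineStack, path: str) -> None:
    meta = {
        "format": "cinelv-stack",
        "version": 1,
        "pixel_spacing_mm": list(stack.pixel_spacing_mm),
        "slice_spacing_mm": stack.slice_spacing_mm,
        "frame_duration_ms": stack.frame_duration_ms,
        "heart_rate_bpm": stack.heart_rate_bpm,
        "analyzed_slice_range": list(stack.analyzed_slice_range),
    }
    buf = io.BytesIO()
    np.lib.format.write_array(buf, stack.intensities, allow_pickle=False)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        zf.writestr("intensities.npy", buf.getvalue())


def _read_archive(path: str, analyzed_slice_range) -> CineStack:
    with zipfile.ZipFile(path) as zf:
        try:
            meta = json.loads(zf.read("meta.json"))
        except KeyError as exc:
            raise MetadataError(f"archive {path} has no meta.json") from exc
        for key in ("pixel_spacing_mm", "slice_spacing_mm", "frame_duration_ms",
                    "heart_rate_bpm"):
            if key not in meta:
                raise MetadataError(f"missing field: {key}")
        arr = np.lib.format.read_array(
            io.BytesIO(zf.read("intensities.npy")), allow_pickle=False
        )
    if analyzed_slice_range is None:
        rng = meta.get("analyzed_slice_range")
        analyzed_slice_range = tuple(rng) if rng is not None else None
    return CineStack(
        intensities=arr,
        pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]),
        slice_spacing_mm=float(meta["slice_spacing_mm"]),
        frame_duration_ms=float(meta["frame_duration_ms"]),
        heart_rate_bpm=float(meta["heart_rate_bpm"]),
        analyzed_slice_range=analyzed_slice_range,
    )


# ---------------------------------------------------------------------------
# Contour JSON I/O
# ---------------------------------------------------------------------------

def contours_to_json(result: SegmentationResult, path) -> None:
    """Serialize a segmentation result to a versioned JSON file.

    Node coordinates round-trip losslessly (float64 repr); absent
    slice/frames are stored as null.
    """
    s, f = result.endo_nodes.shape[:2]

    def _border(nodes):
        out = []
        for si in range(s):
            row = []
            for fi in range(f):
                if result.present[si, fi]:
                    row.append(np.asarray(nodes[si, fi]).tolist())
                else:
                    row.append(None)
            out.append(row)
        return out

    doc = {
        "schema_version": CONTOUR_SCHEMA_VERSION,
        "slice_offset": int(result.slice_offset),
        "n_slices": int(s),
        "n_frames": int(f),
        "ed_frame": result.ed_frame,
        "es_frame": result.es_frame,
        "endo": _border(result.endo_nodes),
        "epi": _border(result.epi_nodes),
        "outflow_flags": result.outflow_flags.astype(int).tolist(),
        "longaxis_displacement": result.longaxis_displacement.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def json_to_contours(path) -> SegmentationResult:
    """Load a segmentation result written by :func:`contours_to_json`."""
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != CONTOUR_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unsupported contour schema version {version!r}; "
            f"expected {CONTOUR_SCHEMA_VERSION}"
        )
    s, f = doc["n_slices"], doc["n_frames"]
    present = np.zeros((s, f), dtype=bool)
    n_nodes = None
    for border in ("endo", "epi"):
        for si in range(s):
            for fi in range(f):
                cell = doc[border][si][fi]
                if cell is not None:
                    n_nodes = len(cell)
    if n_nodes is None:
        n_nodes = DEFAULT_NODE_COUNT
    endo = np.zeros((s, f, n_nodes, 2))
    epi = np.zeros((s, f, n_nodes, 2))
    for si in range(s):
        for fi in range(f):
            e_cell = doc["endo"][si][fi]
            p_cell = doc["epi"][si][fi]
            if e_cell is not None and p_cell is not None:
                endo[si, fi] = np.asarray(e_cell)
                epi[si, fi] = np.asarray(p_cell)
                present[si, fi] = True
    return SegmentationResult(
        endo_nodes=endo,
        epi_nodes=epi,
        present=present,
        outflow_flags=np.asarray(doc["outflow_flags"], dtype=bool),
        longaxis_displacement=np.asarray(doc["longaxis_displacement"], dtype=np.int64),
        slice_offset=int(doc.get("slice_offset", 0)),
        ed_frame=doc.get("ed_frame"),
        es_frame=doc.get("es_frame"),
    )
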