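"""Calibrated AFM height maps, masks, cross-sections, and their file formats.

A :class:`HeightMap` is the universal image currency of the package: a
rectangular grid of surface heights in nanometres with a known pixel size
(nm per pixel).  The coordinate convention follows raster scan order:
continuous nm coordinates with the origin at the centre of the top-left
pixel, x pointing right (columns), y pointing down (rows), so pixel
``(i, j)`` sits at ``(x, y) = (j * pixel_size, i * pixel_size)``.

Three plain-text/TIFF interchange formats are supported:

``matrix``
    A whitespace-separated matrix of heights preceded by a three-line
    header (``# pixel_size_nm``, ``# rows``, ``# cols``).
``xyz``
    One ``x_nm  y_nm  z_nm`` triplet per line; the triplets must form a
    complete regular grid.
``tiff``
    Single-channel 32-bit float TIFF; the pixel size is carried in the
    image description as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .exceptions import FormatError, MaskError

__all__ = [
    "HeightMap",
    "Mask",
    "CrossSection",
    "read_heightmap",
    "write_heightmap",
    "read_mask",
    "write_mask",
]


@dataclass
class HeightMap:
    """A calibrated 2D topograph.

    Parameters
    ----------
    heights : ndarray, shape (rows, cols)
        Surface heights in nm above the substrate plane (0 nm).
    pixel_size : float
        Lateral sampling interval in nm per pixel (square pixels).
    metadata : dict
        Free-form key/value annotations carried through I/O where the
        format permits.
    """

    heights: np.ndarray
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise FormatError(
                f"height map must be 2D, got {self.heights.ndim} dimensions"
            )
        if not self.pixel_size > 0:
            raise FormatError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not np.all(np.isfinite(self.heights)):
            raise FormatError("height map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def extent_nm(self) -> tuple[float, float]:
        """Physical (width, height) spanned by pixel centres, in nm."""
        rows, cols = self.heights.shape
        return ((cols - 1) * self.pixel_size, (rows - 1) * self.pixel_size)

    def copy(self) -> "HeightMap":
        return HeightMap(self.heights.copy(), self.pixel_size, dict(self.metadata))


@dataclass
class Mask:
    """Boolean region mask congruent with a :class:`HeightMap`."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise MaskError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())

    def check_congruent(self, hmap: HeightMap) -> None:
        if self.values.shape != hmap.heights.shape:
            raise MaskError(
                f"mask shape {self.values.shape} does not match "
                f"height map shape {hmap.heights.shape}"
            )


@dataclass
class CrossSection:
    """Height profile sampled along a section line.

    ``arc_positions`` are distances in nm along the line (strictly
    increasing); ``heights`` are the interpolated topographical heights.
    """

    arc_positions: np.ndarray
    heights: np.ndarray
    source_line: object = None

    def __post_init__(self) -> None:
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.arc_positions.shape != self.heights.shape:
            raise FormatError("arc_positions and heights must have equal length")
        if len(self.arc_positions) >= 2 and not np.all(
            np.diff(self.arc_positions) > 0
        ):
            raise FormatError("arc_positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.arc_positions)

    @property
    def step(self) -> float:
        if len(self.arc_positions) < 2:
            return 0.0
        return float(np.median(np.diff(self.arc_positions)))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"arc_position_nm": self.arc_positions, "height_nm": self.heights}
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("matrix", "xyz", "tiff")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".xyz":
        return "xyz"
    return "matrix"


def read_heightmap(path, format: str | None = None) -> HeightMap:
    """Read a height map from ``matrix``, ``xyz``, or ``tiff`` file.

    Raises
    ------
    FormatError
        For ragged matrices, incomplete xyz grids, or unknown formats;
        the message names the defect.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "matrix":
        return _read_matrix(path)
    if fmt == "xyz":
        return _read_xyz(path)
    return _read_tiff(path)


def write_heightmap(hmap: HeightMap, path, format: str | None = None) -> None:
    """Write a height map; see :func:`read_heightmap` for formats."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "matrix":
        _write_matrix(hmap, path)
    elif fmt == "xyz":
        _write_xyz(hmap, path)
    else:
        _write_tiff(hmap, path)


def _write_matrix(hmap: HeightMap, path: Path) -> None:
    rows, cols = hmap.heights.shape
    header = (
        f"pixel_size_nm: {hmap.pixel_size!r}\n"
        f"rows: {rows}\n"
        f"cols: {cols}"
    )
    np.savetxt(path, hmap.heights, fmt="%.9e", header=header)


def _read_matrix(path: Path) -> HeightMap:
    pixel_size = None
    rows = cols = None
    data_lines: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("pixel_size_nm:"):
                    pixel_size = float(body.split(":", 1)[1])
                elif body.startswith("rows:"):
                    rows = int(body.split(":", 1)[1])
                elif body.startswith("cols:"):
                    cols = int(body.split(":", 1)[1])
                continue
            try:
                data_lines.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric value on line {lineno}"
                ) from exc
    if pixel_size is None:
        raise FormatError(f"{path}: missing '# pixel_size_nm' header")
    widths = {len(row) for row in data_lines}
    if len(widths) > 1:
        raise FormatError(f"{path}: ragged matrix (row widths {sorted(widths)})")
    heights = np.asarray(data_lines, dtype=float)
    if rows is not None and heights.shape[0] != rows:
        raise FormatError(
            f"{path}: header declares {rows} rows but file has {heights.shape[0]}"
        )
    if cols is not None and heights.shape[1] != cols:
        raise FormatError(
            f"{path}: header declares {cols} cols but file has {heights.shape[1]}"
        )
    return HeightMap(heights, pixel_size)


def _write_xyz(hmap: HeightMap, path: Path) -> None:
    rows, cols = hmap.heights.shape
    px = hmap.pixel_size
    with open(path, "w") as fh:
        for i in range(rows):
            for j in range(cols):
                fh.write(f"{j * px:.6f} {i * px:.6f} {hmap.heights[i, j]:.9e}\n")


def _read_xyz(path: Path) -> HeightMap:
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed xyz file") from exc
    if data.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 columns (x y z), got {data.shape[1]}")
    xs = np.unique(data[:, 0])
    ys = np.unique(data[:, 1])
    if len(xs) * len(ys) != data.shape[0]:
        raise FormatError(
            f"{path}: incomplete grid ({data.shape[0]} points, expected "
            f"{len(xs)} x {len(ys)} = {len(xs) * len(ys)})"
        )
    steps = np.concatenate([np.diff(xs), np.diff(ys)])
    if len(steps) == 0:
        raise FormatError(f"{path}: grid must span at least 2x2 points")
    px = float(np.median(steps))
    if not np.allclose(steps, px, rtol=1e-6, atol=1e-9):
        raise FormatError(f"{path}: irregular grid spacing")
    heights = np.full((len(ys), len(xs)), np.nan)
    col = np.searchsorted(xs, data[:, 0])
    row = np.searchsorted(ys, data[:, 1])
    heights[row, col] = data[:, 2]
    if np.any(np.isnan(heights)):
        raise FormatError(f"{path}: incomplete grid (duplicate/missing points)")
    return HeightMap(heights, px)


def _write_tiff(hmap: HeightMap, path: Path) -> None:
    desc = json.dumps({"pixel_size_nm": hmap.pixel_size, **hmap.metadata})
    tifffile.imwrite(path, hmap.heights.astype(np.float32), description=desc)


def _read_tiff(path: Path) -> HeightMap:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        desc = page.description or "{}"
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-channel 2D TIFF")
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    pixel_size = meta.pop("pixel_size_nm", None)
    if pixel_size is None:
        raise FormatError(f"{path}: TIFF lacks pixel_size_nm in its description")
    return HeightMap(np.asarray(arr, dtype=float), float(pixel_size), meta)


def write_mask(mask: Mask, path, format: str | None = None) -> None:
    """Write a mask as a 0/1 text matrix or single-channel 8-bit TIFF."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        tifffile.imwrite(path, mask.values.astype(np.uint8) * 255)
    else:
        np.savetxt(path, mask.values.astype(int), fmt="%d",
                   header=f"label: {mask.label}")


def read_mask(path, format: str | None = None) -> Mask:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        arr = tifffile.imread(path)
        return Mask(np.asarray(arr) > 0)
    label = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "label:" in first:
            label = first.split("label:", 1)[1].strip()
    arr = np.loadtxt(path, ndmin=2)
    if not np.all(np.isin(arr, (0, 1))):
        raise FormatError(f"{path}: mask matrix must contain only 0/1")
    return Mask(arr.astype(bool), label=label)


def read_trace_csv(path) -> list[tuple[np.ndarray, str]]:
    """Read polyline traces from CSV with columns x_nm, y_nm, role.

    Consecutive rows sharing a role value form one polyline; returns a
    list of ``(points, role)`` pairs.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"x_nm", "y_nm"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: trace CSV needs columns x_nm, y_nm")
    if "role" not in df.columns:
        df["role"] = "filament"
    out = []
    for role, grp in df.groupby("role", sort=False):
        out.append((grp[["x_nm", "y_nm"]].to_numpy(float), str(role)))
    return out


def write_trace_csv(path, traces: Sequence[tuple[np.ndarray, str]]) -> None:
    import pandas as pd

    frames = []
    for pts, role in traces:
        pts = np.asarray(pts, dtype=float)
        frames.append(
            pd.DataFrame({"x_nm": pts[:, 0], "y_nm": pts[:, 1], "role": role})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
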