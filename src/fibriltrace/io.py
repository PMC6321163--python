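"""Reading and writing AFM height maps.

Height maps are stored internally as 2-D float64 arrays of surface height in
nanometres with an isotropic pixel size (nm per pixel).  Two on-disk formats
are supported:

* 32-bit float grayscale TIFF (pixel size carried in the image description
  tag as JSON, so round trips need no side-channel metadata);
* whitespace-delimited ASCII matrices, one image row per line, top image row
  first.

Proprietary SPM vendor formats are deliberately not parsed; convert to one of
the above first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Default pixel size for a 10 x 10 um scan at 1024 px resolution, nm/px.
DEFAULT_PIXEL_SIZE = 10000.0 / 1024.0


class HeightMapError(ValueError):
    """Raised for malformed height-map files or invalid map construction."""


@dataclass(frozen=True)
class HeightMap:
    """A 2-D surface height map in nm with acquisition metadata.

    Attributes
    ----------
    heights:
        2-D float array, row-major, top-left origin, y increasing downward.
    pixel_size:
        Isotropic physical pixel size in nm per pixel.
    source_id:
        Opaque identifier of the originating image (file stem, scene id, ...).
    """

    heights: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.heights, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise HeightMapError(
                f"heights must be a non-empty 2-D matrix, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise HeightMapError("heights contain non-finite values")
        if not (self.pixel_size > 0):
            raise HeightMapError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "heights", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def with_heights(self, heights: np.ndarray) -> "HeightMap":
        """Copy of this map with new height values, same metadata."""
        return HeightMap(heights, self.pixel_size, self.source_id)


@dataclass(frozen=True)
class ConditionLabel:
    """Experimental condition of one image: DHA concentration x incubation time.

    The study grid uses concentrations {0, 30, 100} uM and times {1, 6, 24} h,
    but any non-negative concentration and positive time are accepted.
    """

    dha_concentration: float  # uM
    incubation_time: float  # hours
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.dha_concentration < 0:
            raise ValueError("dha_concentration must be non-negative")
        if self.incubation_time <= 0:
            raise ValueError("incubation_time must be positive")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def key(self) -> tuple[float, float]:
        """Condition identity without the replicate index."""
        return (self.dha_concentration, self.incubation_time)


def _read_ascii(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise HeightMapError(
                    f"{path}: non-numeric cell on line {lineno}: {exc}"
                ) from exc
    if not rows:
        raise HeightMapError(f"{path}: file contains no data")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise HeightMapError(
            f"{path}: ragged rows (row lengths {sorted(widths)}); "
            "all image rows must have the same number of columns"
        )
    return np.asarray(rows, dtype=np.float64)


def _looks_like_tiff(path: Path) -> bool:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return True
    try:
        with open(path, "rb") as fh:
            magic = fh.read(4)
    except OSError:
        return False
    return magic[:2] in (b"II", b"MM")


def read_height_map(path: str | Path, pixel_size: float | None = None) -> HeightMap:
    """Read a height map from a float TIFF or ASCII matrix file.

    Parameters
    ----------
    path:
        File to read.  TIFFs are recognised by suffix or magic bytes; anything
        else is parsed as a whitespace-delimited matrix.
    pixel_size:
        Physical pixel size in nm/px.  Required if the file carries no scale
        metadata (always for ASCII; TIFFs written by :func:`write_height_map`
        embed it).

    Returns
    -------
    HeightMap with heights in nm.
    """
    path = Path(path)
    if not path.is_file():
        raise HeightMapError(f"no such file: {path}")
    embedded: float | None = None
    if _looks_like_tiff(path):
        try:
            with tifffile.TiffFile(path) as tif:
                arr = tif.asarray()
                desc = tif.pages[0].description
            if desc:
                try:
                    meta = json.loads(desc)
                    embedded = float(meta["pixel_size_nm"])
                except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                    embedded = None
        except Exception as exc:  # tifffile raises several types
            raise HeightMapError(f"{path}: unreadable TIFF: {exc}") from exc
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 2:
            raise HeightMapError(
                f"{path}: expected a single-channel 2-D image, got shape {arr.shape}"
            )
    else:
        arr = _read_ascii(path)
    px = pixel_size if pixel_size is not None else embedded
    if px is None:
        raise HeightMapError(
            f"{path}: file carries no physical scale; pass pixel_size explicitly"
        )
    return HeightMap(arr, float(px), source_id=path.stem)


#: ASCII format string: 10 significant digits, well past the documented
#: 6-significant-digit round-trip guarantee.
_ASCII_FMT = "%.10g"


def write_height_map(hmap: HeightMap, path: str | Path, format: str = "tiff") -> None:
    """Write a height map as float32 TIFF or ASCII matrix.

    TIFF round trips are bit-exact for float32-representable heights; ASCII
    round trips are exact to at least 6 significant digits.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise HeightMapError(f"parent directory does not exist: {path.parent}")
    if format == "tiff":
        desc = json.dumps({"pixel_size_nm": hmap.pixel_size, "units": "nm"})
        tifffile.imwrite(path, hmap.heights.astype(np.float32), description=desc)
    elif format == "ascii":
        np.savetxt(path, hmap.heights, fmt=_ASCII_FMT)
    else:
        raise ValueError(f"unknown format {format!r}; use 'tiff' or 'ascii'")
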