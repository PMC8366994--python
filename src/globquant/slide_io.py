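"""Whole-slide and flat-image I/O with physical resolution metadata.

Coordinate convention (used package-wide): 0-based pixel indices, ``(x, y)``
with x right and y down, half-open rectangles ``[x, x+w) x [y, y+h)``.
Region requests are always expressed in level-0 pixel coordinates.

Slides are read with :mod:`tifffile` (pyramidal TIFF / the TIFF-compatible
subset of Aperio SVS) or :mod:`imageio` (PNG fixtures).  The
microns-per-pixel calibration (``mpp``) is recovered from the Aperio
``ImageDescription`` string (``MPP = 0.5``), from TIFF resolution tags, or
falls back to a configurable default with a logged warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Nominal 20x scan resolution used when a file carries no calibration.
DEFAULT_MPP = 0.50

_MPP_RE = re.compile(r"MPP\s*=\s*([0-9]*\.?[0-9]+)", re.IGNORECASE)


class SlideFormatError(ValueError):
    """Raised when an image file cannot be interpreted as a slide."""


@dataclass
class SlideImage:
    """An RGB slide with one or more pyramid levels held in memory.

    Parameters
    ----------
    name
        Text identifier (usually the file stem).
    levels
        Per-level RGB arrays, level 0 first.  Level ``k`` has downsample
        factor ``level_downsamples[k]`` relative to level 0.
    mpp
        Microns per pixel at level 0 (isotropic, > 0).
    """

    name: str
    levels: list[np.ndarray]
    mpp: float
    level_downsamples: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ValueError(f"mpp must be > 0, got {self.mpp}")
        if not self.levels:
            raise ValueError("slide needs at least one level")
        if not self.level_downsamples:
            base_h, base_w = self.levels[0].shape[:2]
            self.level_downsamples = [
                round(base_w / lvl.shape[1]) if lvl.shape[1] else 1.0
                for lvl in self.levels
            ]
        if self.level_downsamples[0] != 1:
            raise ValueError("level 0 must have downsample 1")
        widths = [lvl.shape[1] for lvl in self.levels]
        if any(b > a for a, b in zip(widths, widths[1:])):
            raise ValueError("level dimensions must be non-increasing")

    @property
    def width_px(self) -> int:
        return self.levels[0].shape[1]

    @property
    def height_px(self) -> int:
        return self.levels[0].shape[0]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_dimensions(self, level: int) -> tuple[int, int]:
        """(width, height) of a pyramid level."""
        arr = self.levels[level]
        return arr.shape[1], arr.shape[0]

    def mpp_at(self, level: int) -> float:
        return self.mpp * self.level_downsamples[level]

    def read_region(
        self, level: int, x: int, y: int, w: int, h: int
    ) -> np.ndarray:
        """Return the RGB tile for a level-0 rectangle, clipped to bounds.

        ``(x, y, w, h)`` are level-0 coordinates; the returned array is at
        the requested level's resolution.
        """
        ds = self.level_downsamples[level]
        arr = self.levels[level]
        x0 = max(0, int(round(x / ds)))
        y0 = max(0, int(round(y / ds)))
        x1 = min(arr.shape[1], int(round((x + w) / ds)))
        y1 = min(arr.shape[0], int(round((y + h) / ds)))
        return arr[y0:y1, x0:x1]


@dataclass(frozen=True)
class TileSpec:
    """Tiling grid: fixed-size tiles with a shared overlap band."""

    tile_size_px: int = 2048
    overlap_px: int = 0
    level: int = 0

    def __post_init__(self) -> None:
        if not (self.tile_size_px > self.overlap_px >= 0):
            raise ValueError(
                f"need tile_size_px > overlap_px >= 0, got "
                f"{self.tile_size_px}, {self.overlap_px}"
            )


@dataclass(frozen=True)
class MeasurementRecord:
    """One measurement row: (specimen, stain, metric) -> value."""

    specimen_id: str
    stain: str  # pasd | polymer | total | annexin
    metric: str
    value: float
    units: str
    params_hash: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite value for {self.metric}")


def _mpp_from_tiff(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    desc = page.description or ""
    m = _MPP_RE.search(desc)
    if m:
        return float(m.group(1))
    tags = page.tags
    if "XResolution" in tags and "ResolutionUnit" in tags:
        num, den = tags["XResolution"].value
        if num and den:
            px_per_unit = num / den
            unit = tags["ResolutionUnit"].value
            # 2 = inch, 3 = centimeter
            um_per_unit = {2: 25400.0, 3: 10000.0}.get(int(unit))
            if um_per_unit and px_per_unit > 0:
                return um_per_unit / px_per_unit
    return None


def _as_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise SlideFormatError(f"not an RGB image: shape {arr.shape}")
    return np.ascontiguousarray(arr[..., :3])


def read_slide(
    path: str | Path,
    level: int | None = None,
    default_mpp: float | None = DEFAULT_MPP,
) -> SlideImage:
    """Read a TIFF/SVS/PNG image as a :class:`SlideImage`.

    All pyramid levels of a pyramidal TIFF are loaded; ``level`` restricts
    the pyramid to a single level (its downsample is renormalised to 1 and
    ``mpp`` rescaled, so the returned object is self-consistent).

    Raises
    ------
    FileNotFoundError
        if ``path`` does not exist.
    SlideFormatError
        if the file cannot be decoded as an RGB image.
    ValueError
        if no mpp metadata is present and ``default_mpp`` is None.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"slide not found: {path}")

    mpp: float | None = None
    suffix = path.suffix.lower()
    try:
        if suffix in {".tif", ".tiff", ".svs"}:
            with tifffile.TiffFile(path) as tif:
                mpp = _mpp_from_tiff(tif)
                series = tif.series[0]
                if series.levels and len(series.levels) > 1:
                    level_arrays = [
                        _as_rgb(lvl.asarray()) for lvl in series.levels
                    ]
                else:
                    level_arrays = [_as_rgb(series.asarray())]
        else:
            level_arrays = [_as_rgb(iio.imread(path))]
    except (FileNotFoundError, SlideFormatError):
        raise
    except Exception as exc:  # corrupt / undecodable file
        raise SlideFormatError(f"cannot read image {path}: {exc}") from exc

    if mpp is None:
        if default_mpp is None:
            raise ValueError(
                f"{path}: no mpp metadata and no default configured"
            )
        logger.warning(
            "%s: no mpp metadata; assuming default %.3f um/px",
            path.name,
            default_mpp,
        )
        mpp = default_mpp

    slide = SlideImage(name=path.stem, levels=level_arrays, mpp=mpp)
    if level is not None:
        if not 0 <= level < slide.n_levels:
            raise ValueError(
                f"level {level} out of range (slide has {slide.n_levels})"
            )
        ds = slide.level_downsamples[level]
        slide = SlideImage(
            name=slide.name,
            levels=[slide.levels[level]],
            mpp=slide.mpp * ds,
            level_downsamples=[1.0],
        )
    return slide


def write_slide(
    path: str | Path,
    image: np.ndarray,
    mpp: float,
    extra_levels: Sequence[np.ndarray] = (),
) -> None:
    """Write an RGB array as TIFF with an Aperio-style ``MPP`` tag.

    ``extra_levels`` appends downsampled copies as SubIFD pyramid levels.
    """
    path = Path(path)
    desc = f"globquant|MPP = {mpp:.6f}"
    with tifffile.TiffWriter(path) as tw:
        tw.write(
            image,
            description=desc,
            subifds=len(extra_levels),
            photometric="rgb",
        )
        for lvl in extra_levels:
            tw.write(lvl, subfiletype=1, photometric="rgb")


def iter_tiles(
    slide: SlideImage, spec: TileSpec
) -> Iterator[tuple[np.ndarray, tuple[int, int]]]:
    """Yield ``(tile_rgb, (x, y))`` covering the slide.

    Origins are level-0 coordinates on a stride of
    ``tile_size_px - overlap_px``; adjacent tiles share exactly
    ``overlap_px`` pixels.  Tiles at the right/bottom edge are clipped,
    never padded.
    """
    ds = slide.level_downsamples[spec.level]
    tile0 = int(spec.tile_size_px * ds)  # tile extent in level-0 px
    stride = int((spec.tile_size_px - spec.overlap_px) * ds)
    for y in range(0, slide.height_px, stride):
        for x in range(0, slide.width_px, stride):
            tile = slide.read_region(spec.level, x, y, tile0, tile0)
            if tile.size:
                yield tile, (x, y)


MEASUREMENT_COLUMNS = [
    "specimen_id",
    "stain",
    "metric",
    "value",
    "units",
    "params_hash",
]


def write_measurements(
    records: Sequence[MeasurementRecord], path: str | Path
) -> None:
    """Write measurement records as CSV (header + one row per record)."""
    if not records:
        raise ValueError("refusing to write an empty measurement table")
    df = pd.DataFrame([vars(r) for r in records], columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")  # lossless round trip


def read_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Read back a measurement CSV written by :func:`write_measurements`."""
    df = pd.read_csv(
        path,
        dtype={"specimen_id": str, "params_hash": str},
        float_precision="round_trip",
    )
    df["params_hash"] = df["params_hash"].fillna("")
    return [
        MeasurementRecord(
            specimen_id=row.specimen_id,
            stain=row.stain,
            metric=row.metric,
            value=float(row.value),
            units=row.units,
            params_hash=row.params_hash,
        )
        for row in df.itertuples(index=False)
    ]
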