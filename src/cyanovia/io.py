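"""Calibrated image containers, assay configuration, and file round-trips.

All analysis operates on 8-bit ``[0, 255]`` RGB intensities: the empirically
chosen classification cutoff (green mean > 50) and the maximum-entropy
threshold both assume an 8-bit histogram.  Higher bit depths are linearly
rescaled at ingest and the rescale factor is logged.

Spatial calibration (``um_per_px``) is an explicit, required parameter rather
than something read out of TIFF metadata — metadata dialects vary too much
between microscope vendors to trust silently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


class CyanoviaError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True)
class AssayConfig:
    """Constants of the viability assay.

    Parameters
    ----------
    min_area_um2:
        Particles with a smaller footprint are discarded as noise artifacts.
        Default 35.0 µm²; a particle of exactly this area is retained.
    green_cutoff:
        A particle whose mean green intensity (measured on the raw channel)
        exceeds this value is classed non-viable.  Default 50.0 — an
        empirically chosen, microscope-dependent value; recalibrate it for
        other imaging setups.
    imaged_volume_ul:
        Total chamber volume covered by all fields of one run, in µl.
        Default 0.084 µl for the counting-chamber scan pattern used here.
    dilution_factor:
        Multiplier undoing the sample dilution (mixing 1:2 with glycerol to
        immobilise cells halves the concentration, hence default 2.0).
        If the mixing protocol is read as 1 part culture + 2 parts glycerol,
        set this to 3.0.
    connectivity:
        Pixel connectivity for particle registration, 4 or 8 (default 8,
        the common particle-analyzer convention).
    include_edge_particles:
        Whether particles touching the image border are counted
        (default True).
    """

    min_area_um2: float = 35.0
    green_cutoff: float = 50.0
    imaged_volume_ul: float = 0.084
    dilution_factor: float = 2.0
    connectivity: int = 8
    include_edge_particles: bool = True

    def __post_init__(self) -> None:
        if self.min_area_um2 < 0:
            raise ValueError(f"min_area_um2 must be >= 0, got {self.min_area_um2}")
        if not 0 <= self.green_cutoff <= 255:
            raise ValueError(f"green_cutoff must be in [0, 255], got {self.green_cutoff}")
        if self.imaged_volume_ul <= 0:
            raise ValueError(f"imaged_volume_ul must be > 0, got {self.imaged_volume_ul}")
        if self.dilution_factor < 1:
            raise ValueError(f"dilution_factor must be >= 1, got {self.dilution_factor}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CalibratedField:
    """One multi-channel micrograph with its spatial calibration.

    ``pixels`` is an ``(H, W, 3)`` uint8 array; channel 0 is the red
    (chlorophyll) channel, channel 1 the green (unspecific autofluorescence)
    channel.  ``um_per_px`` is the edge length of one pixel in micrometres.
    """

    field_id: str
    pixels: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel per dimension")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be > 0, got {self.um_per_px}")

    @property
    def red(self) -> np.ndarray:
        return self.pixels[:, :, 0]

    @property
    def green(self) -> np.ndarray:
        return self.pixels[:, :, 1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class FieldSet:
    """All fields of one assay run (one chamber fill) plus its configuration."""

    fields: tuple[CalibratedField, ...]
    config: AssayConfig = field(default_factory=AssayConfig)

    def __post_init__(self) -> None:
        flds = tuple(self.fields)
        object.__setattr__(self, "fields", flds)
        calibrations = {f.um_per_px for f in flds}
        if len(calibrations) > 1:
            raise ValueError(
                f"all fields of a run must share one um_per_px, got {sorted(calibrations)}"
            )

    def __len__(self) -> int:
        return len(self.fields)


def read_field(path: str | Path, um_per_px: float) -> CalibratedField:
    """Read a TIFF or PNG micrograph into a :class:`CalibratedField`.

    8-bit RGB(A) is read losslessly (alpha dropped); 16-bit input is linearly
    rescaled to [0, 255] by its per-image maximum.  Single-channel grayscale
    is rejected: the assay needs two fluorescence channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if um_per_px <= 0:
        raise ValueError(f"um_per_px must be > 0, got {um_per_px}")
    arr = iio.imread(path)
    if arr.ndim == 2:
        raise ValueError(f"{path.name}: two channels required, got single-channel grayscale")
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"{path.name}: unsupported colour model with shape {arr.shape}")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        px = arr
    elif arr.dtype == np.uint16:
        peak = int(arr.max())
        if peak == 0:
            px = arr.astype(np.uint8)
            scale = 1.0
        else:
            scale = 255.0 / peak
            px = np.rint(arr.astype(np.float64) * scale).astype(np.uint8)
        logger.info("rescaled 16-bit image %s to 8-bit (factor %.6g)", path.name, scale)
    else:
        raise ValueError(f"{path.name}: unsupported bit depth {arr.dtype}")
    return CalibratedField(field_id=path.stem, pixels=px, um_per_px=um_per_px)


def write_field(field: CalibratedField, path: str | Path) -> None:
    """Write a field losslessly as 8-bit RGB; container chosen by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, field.pixels, photometric="rgb")
    elif suffix == ".png":
        iio.imwrite(path, field.pixels)
    else:
        raise ValueError(f"unsupported output format {suffix!r}; use .tif, .tiff or .png")


def load_config(path: str | Path | None = None) -> AssayConfig:
    """Load an :class:`AssayConfig` from JSON; absent keys take the defaults."""
    if path is None:
        return AssayConfig()
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config JSON must be an object")
    known = {f.name for f in dataclasses.fields(AssayConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AssayConfig(**raw)


def find_fields(directory: str | Path, um_per_px: float) -> list[CalibratedField]:
    """Read every TIFF/PNG in a directory (sorted by name) as one run."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    return [read_field(p, um_per_px) for p in paths]
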