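"""Colony counting on fluorescence plate images and plating-based viability.

Plated viable cells grow into colonies whose accessory-pigment
(phycocyanin) fluorescence makes them bright blobs on a dark plate.  The
counter reuses the same segmentation machinery as the microscopy pipeline:
histogram threshold, connected components (8-connectivity), and a minimum
component size in pixels.  Viability by plating is the sample's colony count
as a percentage of an all-viable control's count; the plated cell number and
plate areas cancel in that normalisation and are not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .io import CalibratedField
from .thresholding import (
    DegenerateHistogramError,
    binarize,
    histogram,
    max_entropy_threshold,
)

logger = logging.getLogger(__name__)

# ITU-R 601 luma weights; only used when counting on an RGB plate image.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ColonyCount:
    plate_id: str
    n_colonies: int
    threshold_used: int | None
    min_colony_area_px: int


def _select_channel(image: CalibratedField | np.ndarray, channel: str) -> np.ndarray:
    if isinstance(image, CalibratedField):
        if channel == "red":
            return image.red
        if channel == "green":
            return image.green
        if channel == "luminance":
            return np.clip(
                np.rint(image.pixels.astype(np.float64) @ _LUMA), 0, 255
            ).astype(np.uint8)
        raise ValueError(f"unknown channel {channel!r}")
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("bare arrays must be single-channel 2-D grids")
    return arr


def count_colonies(
    image: CalibratedField | np.ndarray,
    min_colony_area_px: int,
    method: str = "max_entropy",
    channel: str = "luminance",
    plate_id: str = "plate",
) -> ColonyCount:
    """Segment and count colonies on one plate image.

    A degenerate histogram (uniform plate) yields zero colonies with a
    warning rather than an error: an empty plate is a legitimate outcome —
    a fully non-viable sample forms no colonies.
    """
    if method != "max_entropy":
        raise ValueError(f"unknown thresholding method {method!r}")
    if min_colony_area_px < 1:
        raise ValueError("min_colony_area_px must be >= 1")
    grid = _select_channel(image, channel)
    if grid.size == 0:
        raise ValueError("empty plate image")
    if isinstance(image, CalibratedField):
        plate_id = image.field_id
    try:
        t = max_entropy_threshold(histogram(grid))
    except DegenerateHistogramError:
        logger.warning("plate %s: degenerate histogram, counting 0 colonies", plate_id)
        return ColonyCount(plate_id, 0, None, min_colony_area_px)
    labels = measure.label(binarize(grid, t), connectivity=2)
    areas = np.bincount(labels.ravel())[1:]  # skip background label 0
    n = int((areas >= min_colony_area_px).sum())
    logger.info("plate %s: threshold %d, %d colonies", plate_id, t, n)
    return ColonyCount(plate_id, n, t, min_colony_area_px)


def plating_viability(sample: ColonyCount, control: ColonyCount) -> float:
    """Sample colony count normalised to the all-viable control, in percent."""
    if control.n_colonies <= 0:
        raise ValueError("control plate has zero colonies; cannot normalise")
    return 100.0 * sample.n_colonies / control.n_colonies
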