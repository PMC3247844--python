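"""Synthetic counting-chamber fields and plate images with exact ground truth.

The generator emulates what the assay actually sees: a dark chamber
background, disk-shaped cells that are bright in exactly one fluorescence
channel (red for viable, green for non-viable), Gaussian read noise, and
small bright noise specks below the artifact-filter area.  It does NOT
attempt photorealism — no point-spread function by default (an optional
Gaussian blur is available for robustness checks), no uneven illumination,
no touching or dividing cells.

The default cell radius is 4.0 µm, larger than the ~1 µm physical radius of
a unicellular cyanobacterium: the assay's 35 µm² minimum footprint only
makes sense for fluorescent footprints enlarged by optical blur, so the
generator renders footprints on that scale (~50 µm² at defaults).

Reproducibility: one mandatory seed per scene, split into three independent
sub-streams (cell placement, speck placement, pixel noise).  Adding specks
to a scene therefore changes neither the cells nor the noise field — the
property the artifact filter is meant to guarantee downstream.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw

from .io import AssayConfig, CalibratedField, CyanoviaError, FieldSet


class PlacementError(CyanoviaError):
    """Objects could not be placed without violating the minimum separation."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic counting-chamber field.

    Intensity parameters are (mean, sd) of the per-cell brightness in the
    cell's bright channel; each cell draws one brightness, so a noise-free
    render has flat disks.  ``off_channel_intensity`` (default 20) keeps the
    dim channel of every cell safely below the green classification cutoff
    of 50.  ``min_separation_um`` defaults to 2.5 cell radii, which prevents
    segmentation from ever merging two cells.
    """

    n_red: int
    n_green: int
    width_px: int = 512
    height_px: int = 512
    um_per_px: float = 0.5
    cell_radius_um: float = 4.0
    red_cell_intensity: tuple[float, float] = (180.0, 15.0)
    green_cell_intensity: tuple[float, float] = (120.0, 15.0)
    off_channel_intensity: float = 20.0
    background_level: float = 8.0
    noise_sigma: float = 3.0
    n_specks: int = 0
    speck_area_um2: float = 10.0
    # Artifacts in real images are dim noise blobs barely above background,
    # not objects rivalling cell brightness; per-speck draw like cells.
    speck_intensity: tuple[float, float] = (60.0, 10.0)
    min_separation_um: float | None = None
    blur_sigma_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_red < 0 or self.n_green < 0 or self.n_specks < 0:
            raise ValueError("object counts must be non-negative")
        if self.width_px < 1 or self.height_px < 1 or self.um_per_px <= 0:
            raise ValueError("invalid field geometry")
        if self.cell_radius_um <= 0:
            raise ValueError("cell_radius_um must be positive")
        if self.speck_area_um2 >= 35.0:
            raise ValueError("speck_area_um2 must stay below the 35 um^2 filter")

    @property
    def cell_radius_px(self) -> float:
        return self.cell_radius_um / self.um_per_px

    @property
    def speck_radius_px(self) -> float:
        return math.sqrt(self.speck_area_um2 / math.pi) / self.um_per_px

    @property
    def min_separation_px(self) -> float:
        sep_um = (
            self.min_separation_um
            if self.min_separation_um is not None
            else 2.5 * self.cell_radius_um
        )
        return sep_um / self.um_per_px


@dataclass(frozen=True)
class CellRecord:
    center: tuple[float, float]  # (row, col) px
    radius_px: float
    cls: str  # "viable" (red) or "nonviable" (green)


@dataclass(frozen=True)
class SpeckRecord:
    center: tuple[float, float]
    radius_px: float
    channel: int  # 0 = red, 1 = green


@dataclass(frozen=True)
class GroundTruth:
    cells: tuple[CellRecord, ...]
    specks: tuple[SpeckRecord, ...]
    seed: int
    spec: SceneSpec

    @property
    def n_viable(self) -> int:
        return sum(1 for c in self.cells if c.cls == "viable")

    @property
    def n_nonviable(self) -> int:
        return sum(1 for c in self.cells if c.cls == "nonviable")

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "spec": dataclasses.asdict(self.spec),
            "cells": [dataclasses.asdict(c) for c in self.cells],
            "specks": [dataclasses.asdict(s) for s in self.specks],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


_RETRIES_PER_OBJECT = 500
# Guard gap (px) kept between object edges so that pixel noise cannot bridge
# two objects into one connected component after thresholding.
_CLEARANCE_PX = 6.0


def _place(
    rng: np.random.Generator,
    n: int,
    radius_px: float,
    shape: tuple[int, int],
    occupied: list[tuple[float, float, float]],
    pair_sep_px: float | None,
) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` centers keeping clearance from everything placed.

    Every new object keeps a guard gap beyond touching distance from all
    previously placed objects (earlier batches and its own); objects of this
    batch additionally keep ``pair_sep_px`` between their centers when given.
    """
    h, w = shape
    margin = radius_px + 1.0
    if 2 * margin >= min(h, w):
        raise PlacementError("object radius too large for the field")
    placed: list[tuple[float, float]] = []
    budget = _RETRIES_PER_OBJECT * max(n, 1)
    while len(placed) < n:
        if budget <= 0:
            raise PlacementError(
                f"could not place object {len(placed) + 1}/{n} within retry budget"
            )
        budget -= 1
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        ok = True
        for orow, ocol, orad in occupied:
            if math.hypot(r - orow, c - ocol) < radius_px + orad + _CLEARANCE_PX:
                ok = False
                break
        if ok:
            for prow, pcol in placed:
                d = math.hypot(r - prow, c - pcol)
                if d < 2 * radius_px + _CLEARANCE_PX:
                    ok = False
                    break
                if pair_sep_px is not None and d < pair_sep_px:
                    ok = False
                    break
        if ok:
            placed.append((r, c))
    occupied.extend((r, c, radius_px) for r, c in placed)
    return placed


def render_field(spec: SceneSpec, field_id: str = "synthetic") -> tuple[CalibratedField, GroundTruth]:
    """Render one field and return it with its exact ground truth."""
    cells_rng, specks_rng, noise_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(3)
    )
    shape = (spec.height_px, spec.width_px)
    occupied: list[tuple[float, float, float]] = []

    n_cells = spec.n_red + spec.n_green
    centers = _place(
        cells_rng, n_cells, spec.cell_radius_px, shape, occupied, spec.min_separation_px
    )
    # Class order is fixed (red first); placement order is random anyway.
    classes = ["viable"] * spec.n_red + ["nonviable"] * spec.n_green
    brightness = []
    for cls in classes:
        mean, sd = (
            spec.red_cell_intensity if cls == "viable" else spec.green_cell_intensity
        )
        brightness.append(float(cells_rng.normal(mean, sd)) if sd > 0 else mean)

    speck_centers = _place(
        specks_rng, spec.n_specks, spec.speck_radius_px, shape, occupied, None
    )
    speck_channels = [int(specks_rng.integers(0, 2)) for _ in speck_centers]
    sp_mean, sp_sd = spec.speck_intensity
    speck_values = [
        float(specks_rng.normal(sp_mean, sp_sd)) if sp_sd > 0 else sp_mean
        for _ in speck_centers
    ]

    img = np.full((*shape, 3), float(spec.background_level))
    cells = []
    for (row, col), cls, value in zip(centers, classes, brightness):
        rr, cc = draw.disk((row, col), spec.cell_radius_px, shape=shape)
        bright_ch = 0 if cls == "viable" else 1
        img[rr, cc, bright_ch] = value
        img[rr, cc, 1 - bright_ch] = spec.off_channel_intensity
        cells.append(CellRecord(center=(row, col), radius_px=spec.cell_radius_px, cls=cls))
    specks = []
    for (row, col), ch, value in zip(speck_centers, speck_channels, speck_values):
        rr, cc = draw.disk((row, col), spec.speck_radius_px, shape=shape)
        img[rr, cc, ch] = value
        specks.append(
            SpeckRecord(center=(row, col), radius_px=spec.speck_radius_px, channel=ch)
        )

    if spec.blur_sigma_px > 0:
        for ch in range(3):
            img[:, :, ch] = ndimage.gaussian_filter(img[:, :, ch], spec.blur_sigma_px)
    if spec.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, spec.noise_sigma, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    cal = CalibratedField(field_id=field_id, pixels=pixels, um_per_px=spec.um_per_px)
    truth = GroundTruth(cells=tuple(cells), specks=tuple(specks), seed=spec.seed, spec=spec)
    return cal, truth


@dataclass(frozen=True)
class MixtureSample:
    """One simulated run of the viability-mixture validation design."""

    true_viable_fraction: float
    fieldset: FieldSet
    ground_truths: tuple[GroundTruth, ...]

    @property
    def true_counts(self) -> tuple[int, int]:
        n_v = sum(g.n_viable for g in self.ground_truths)
        n_n = sum(g.n_nonviable for g in self.ground_truths)
        return n_v, n_n


def render_mixture_series(
    base: SceneSpec,
    fractions: list[float],
    total_cells: int,
    fields_per_sample: int,
    seed: int,
    config: AssayConfig | None = None,
) -> list[MixtureSample]:
    """Simulate the viable/non-viable mixing design: one run per fraction.

    Each run has ``total_cells`` cells split into viable/non-viable by the
    requested fraction (rounded to the nearest cell) and scattered uniformly
    at random across ``fields_per_sample`` fields.  Ground-truth totals match
    the requested counts exactly.
    """
    if fields_per_sample < 1 or total_cells < 0:
        raise ValueError("need at least one field and a non-negative cell total")
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0, 1]")
    config = config or AssayConfig()
    root = np.random.SeedSequence(seed)
    sample_seqs = root.spawn(len(fractions))
    samples = []
    for frac, seq in zip(fractions, sample_seqs):
        n_red_total = round(total_cells * frac)
        n_green_total = total_cells - n_red_total
        rng = np.random.default_rng(seq)
        field_of_red = rng.integers(0, fields_per_sample, n_red_total)
        field_of_green = rng.integers(0, fields_per_sample, n_green_total)
        field_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(fields_per_sample)]
        fields = []
        truths = []
        for i in range(fields_per_sample):
            spec_i = dataclasses.replace(
                base,
                n_red=int((field_of_red == i).sum()),
                n_green=int((field_of_green == i).sum()),
                seed=field_seeds[i],
            )
            fld, truth = render_field(spec_i, field_id=f"frac{frac:g}_field{i}")
            fields.append(fld)
            truths.append(truth)
        samples.append(
            MixtureSample(
                true_viable_fraction=frac,
                fieldset=FieldSet(fields=tuple(fields), config=config),
                ground_truths=tuple(truths),
            )
        )
    return samples


@dataclass(frozen=True)
class PlateGroundTruth:
    colonies: tuple[tuple[float, float, float], ...]  # (row, col, radius_px)
    specks: tuple[tuple[float, float, float], ...]
    seed: int


def render_plate(
    n_colonies: int,
    min_colony_radius_px: int = 6,
    n_specks: int = 0,
    seed: int = 0,
    width_px: int = 600,
    height_px: int = 600,
    background_level: float = 8.0,
    colony_intensity: float = 200.0,
    noise_sigma: float = 2.0,
) -> tuple[np.ndarray, PlateGroundTruth]:
    """Render a single-channel plate image: bright colonies plus tiny specks.

    Colony radii are drawn in [min, 2x min]; speck radius is fixed at 1 px,
    well under any sensible minimum colony area.
    """
    if n_colonies < 0 or n_specks < 0:
        raise ValueError("counts must be non-negative")
    if min_colony_radius_px < 2:
        raise ValueError("min_colony_radius_px must be >= 2")
    col_rng, speck_rng, noise_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)
    )
    shape = (height_px, width_px)
    occupied: list[tuple[float, float, float]] = []
    max_r = 2.0 * min_colony_radius_px
    centers = _place(col_rng, n_colonies, max_r, shape, occupied, None)
    radii = [float(col_rng.uniform(min_colony_radius_px, max_r)) for _ in centers]
    speck_centers = _place(speck_rng, n_specks, 1.0, shape, occupied, None)

    img = np.full(shape, float(background_level))
    colonies = []
    for (row, col), radius in zip(centers, radii):
        rr, cc = draw.disk((row, col), radius, shape=shape)
        img[rr, cc] = colony_intensity
        colonies.append((row, col, radius))
    specks = []
    for row, col in speck_centers:
        rr, cc = draw.disk((row, col), 1.0, shape=shape)
        img[rr, cc] = colony_intensity
        specks.append((row, col, 1.0))
    if noise_sigma > 0:
        img = img + noise_rng.normal(0.0, noise_sigma, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = PlateGroundTruth(colonies=tuple(colonies), specks=tuple(specks), seed=seed)
    return pixels, truth
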