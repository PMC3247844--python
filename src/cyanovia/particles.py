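"""Connected-component registration and measurement of fluorescent particles.

A "particle" is one connected component of the combined red/green foreground
mask.  Mean intensities are always measured on the ORIGINAL (pre-threshold)
channels, never on the binary mask, because the downstream viability rule
thresholds a raw green intensity.  Components smaller than the configured
minimum footprint (default 35 µm²) are rejected as artifacts of background
noise; the comparison is strict, so a particle of exactly the minimum area
is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage import measure

from .io import AssayConfig, CalibratedField


@dataclass(frozen=True)
class Particle:
    particle_id: int
    area_px: int
    area_um2: float
    centroid: tuple[float, float]  # (row, col), pixel coordinates
    mean_red: float
    mean_green: float
    touches_edge: bool


@dataclass(frozen=True)
class ParticleSet:
    """Particles registered in one field, with the thresholds that produced them."""

    field_id: str
    particles: tuple[Particle, ...]
    thresholds_used: tuple[int | None, int | None] = (None, None)

    def __post_init__(self) -> None:
        parts = tuple(self.particles)
        object.__setattr__(self, "particles", parts)
        ids = [p.particle_id for p in parts]
        if len(ids) != len(set(ids)):
            raise ValueError("particle_ids must be unique within a set")

    def __len__(self) -> int:
        return len(self.particles)


def combine_masks(red_mask: np.ndarray, green_mask: np.ndarray) -> np.ndarray:
    """Pixelwise OR of the two channel foreground masks."""
    red_mask = np.asarray(red_mask, dtype=bool)
    green_mask = np.asarray(green_mask, dtype=bool)
    if red_mask.shape != green_mask.shape:
        raise ValueError(
            f"mask dimensions differ: {red_mask.shape} vs {green_mask.shape}"
        )
    return red_mask | green_mask


def register_particles(
    mask: np.ndarray,
    field: CalibratedField,
    config: AssayConfig | None = None,
) -> ParticleSet:
    """Label connected components of ``mask`` and measure each one.

    Per component: pixel count, physical area (px count x um_per_px²),
    centroid, mean raw red/green intensity, and whether it touches the image
    border.  Edge-touching components are dropped when
    ``config.include_edge_particles`` is False.
    """
    config = config or AssayConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.shape:
        raise ValueError(f"mask shape {mask.shape} != field shape {field.shape}")
    connectivity = 1 if config.connectivity == 4 else 2
    labels = measure.label(mask, connectivity=connectivity)
    h, w = mask.shape
    px_area_um2 = field.um_per_px**2
    particles = []
    for region in measure.regionprops(labels, intensity_image=field.pixels):
        minr, minc, maxr, maxc = region.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        if touches and not config.include_edge_particles:
            continue
        mean_rgb = region.intensity_mean  # per-channel means over the component
        particles.append(
            Particle(
                particle_id=int(region.label),
                area_px=int(region.area),
                area_um2=float(region.area) * px_area_um2,
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                mean_red=float(mean_rgb[0]),
                mean_green=float(mean_rgb[1]),
                touches_edge=bool(touches),
            )
        )
    return ParticleSet(field_id=field.field_id, particles=tuple(particles))


def filter_artifacts(ps: ParticleSet, config: AssayConfig | None = None) -> ParticleSet:
    """Drop particles with ``area_um2`` strictly below the configured minimum."""
    config = config or AssayConfig()
    kept = tuple(p for p in ps.particles if p.area_um2 >= config.min_area_um2)
    return replace(ps, particles=kept)


def particles_to_frame(
    ps: ParticleSet, classes: list[str] | None = None
) -> pd.DataFrame:
    """Tabulate a particle set in the per-particle CSV layout."""
    if classes is not None and len(classes) != len(ps.particles):
        raise ValueError("one class label per particle required")
    rows = []
    for i, p in enumerate(ps.particles):
        rows.append(
            {
                "field_id": ps.field_id,
                "particle_id": p.particle_id,
                "area_px": p.area_px,
                "area_um2": p.area_um2,
                "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1],
                "mean_red": p.mean_red,
                "mean_green": p.mean_green,
                "touches_edge": p.touches_edge,
                "class": classes[i] if classes is not None else "",
            }
        )
    columns = [
        "field_id",
        "particle_id",
        "area_px",
        "area_um2",
        "centroid_row",
        "centroid_col",
        "mean_red",
        "mean_green",
        "touches_edge",
        "class",
    ]
    return pd.DataFrame(rows, columns=columns)
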