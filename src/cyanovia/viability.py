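"""Viable/non-viable classification and run-level quantification.

Viable cyanobacterial cells fluoresce red (chlorophyll a); once a cell dies
its chlorophyll degrades and a green unspecific autofluorescence remains.
Classification therefore needs only one rule: a particle whose mean green
intensity exceeds the configured cutoff (default 50, strict inequality, so a
mean of exactly 50.0 is viable) is non-viable, everything else is viable.
The red mean is recorded per particle but deliberately unused for classing.

Concentration follows the counting-chamber convention: the configured
``imaged_volume_ul`` is the TOTAL volume covered by all fields of the run,

    cells/ml = n_total / imaged_volume_ul * 1000 * dilution_factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import AssayConfig, CalibratedField, FieldSet
from .particles import (
    ParticleSet,
    Particle,
    combine_masks,
    filter_artifacts,
    particles_to_frame,
    register_particles,
)
from .thresholding import (
    DegenerateHistogramError,
    binarize,
    histogram,
    max_entropy_threshold,
)

logger = logging.getLogger(__name__)

VIABLE = "viable"
NONVIABLE = "nonviable"


@dataclass(frozen=True)
class ViabilityResult:
    """Aggregated outcome of one assay run.

    ``viable_fraction`` is None when no particles were counted.
    ``per_field_counts`` has one row per field: field_id, n_viable,
    n_nonviable, t_red, t_green (thresholds; empty when the channel
    histogram was degenerate).
    """

    n_viable: int
    n_nonviable: int
    concentration_cells_per_ml: float
    per_field_counts: pd.DataFrame

    @property
    def n_total(self) -> int:
        return self.n_viable + self.n_nonviable

    @property
    def viable_fraction(self) -> float | None:
        if self.n_total == 0:
            return None
        return self.n_viable / self.n_total


def classify_particle(p: Particle, config: AssayConfig | None = None) -> str:
    """Class a filtered particle by its mean green intensity."""
    config = config or AssayConfig()
    return NONVIABLE if p.mean_green > config.green_cutoff else VIABLE


def quantify(run: FieldSet, particle_sets: list[ParticleSet]) -> ViabilityResult:
    """Pool classified counts over all fields and convert to cells/ml.

    ``particle_sets`` must correspond 1:1 to ``run.fields`` and already be
    artifact-filtered.
    """
    if len(run) == 0:
        raise ValueError("run contains zero fields")
    if len(particle_sets) != len(run):
        raise ValueError(
            f"{len(particle_sets)} particle sets for {len(run)} fields"
        )
    config = run.config
    rows = []
    for ps in particle_sets:
        classes = [classify_particle(p, config) for p in ps.particles]
        n_v = classes.count(VIABLE)
        n_n = classes.count(NONVIABLE)
        t_red, t_green = ps.thresholds_used
        rows.append(
            {
                "field_id": ps.field_id,
                "n_viable": n_v,
                "n_nonviable": n_n,
                "t_red": t_red,
                "t_green": t_green,
            }
        )
    per_field = pd.DataFrame(
        rows, columns=["field_id", "n_viable", "n_nonviable", "t_red", "t_green"]
    )
    n_viable = int(per_field["n_viable"].sum())
    n_nonviable = int(per_field["n_nonviable"].sum())
    n_total = n_viable + n_nonviable
    concentration = (
        n_total / config.imaged_volume_ul * 1000.0 * config.dilution_factor
    )
    return ViabilityResult(
        n_viable=n_viable,
        n_nonviable=n_nonviable,
        concentration_cells_per_ml=concentration,
        per_field_counts=per_field,
    )


def _segment_field(
    field: CalibratedField, config: AssayConfig
) -> ParticleSet:
    """Threshold both channels, combine, register and filter one field.

    A degenerate channel histogram (fewer than two occupied intensity
    levels) is legitimate — a fully viable culture has an empty green
    channel and vice versa — so that channel simply contributes no
    foreground.  Only when BOTH channels are degenerate is a warning logged.
    """
    masks = []
    thresholds: list[int | None] = []
    for name, channel in (("red", field.red), ("green", field.green)):
        try:
            t = max_entropy_threshold(histogram(channel))
        except DegenerateHistogramError:
            t = None
        thresholds.append(t)
        if t is None:
            masks.append(channel > 255)  # all-False mask of the right shape
        else:
            masks.append(binarize(channel, t))
            logger.debug("field %s: %s threshold %d", field.field_id, name, t)
    if thresholds[0] is None and thresholds[1] is None:
        logger.warning(
            "field %s: both channel histograms degenerate; no particles registered",
            field.field_id,
        )
    combined = combine_masks(masks[0], masks[1])
    ps = register_particles(combined, field, config)
    ps = filter_artifacts(ps, config)
    return ParticleSet(
        field_id=ps.field_id,
        particles=ps.particles,
        thresholds_used=(thresholds[0], thresholds[1]),
    )


def run_assay(run: FieldSet) -> tuple[ViabilityResult, pd.DataFrame]:
    """Execute the full pipeline on one run and return result + particle table.

    Per field: split channels -> histogram -> maximum-entropy threshold per
    channel -> binarize -> OR-combine -> register particles -> artifact
    filter -> classify; then pool counts and compute the concentration.
    Deterministic: identical input bytes give identical output.
    """
    if len(run) == 0:
        raise ValueError("run contains zero fields")
    particle_sets = [_segment_field(f, run.config) for f in run.fields]
    result = quantify(run, particle_sets)
    frames = []
    for ps in particle_sets:
        classes = [classify_particle(p, run.config) for p in ps.particles]
        frames.append(particles_to_frame(ps, classes))
    particles_df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else particles_to_frame(ParticleSet("", ()))
    )
    return result, particles_df


def summary_frame(run_id: str, run: FieldSet, result: ViabilityResult) -> pd.DataFrame:
    """One-row summary in the documented CSV layout."""
    import json

    viable_percent = (
        100.0 * result.viable_fraction if result.viable_fraction is not None else ""
    )
    t_red = [None if pd.isna(t) else int(t) for t in result.per_field_counts["t_red"]]
    t_green = [
        None if pd.isna(t) else int(t) for t in result.per_field_counts["t_green"]
    ]
    row = {
        "run_id": run_id,
        "n_fields": len(run),
        "n_viable": result.n_viable,
        "n_nonviable": result.n_nonviable,
        "viable_percent": viable_percent,
        "concentration_cells_per_ml": result.concentration_cells_per_ml,
        "t_red_per_field": json.dumps(t_red),
        "t_green_per_field": json.dumps(t_green),
        "config": json.dumps(run.config.to_dict()),
    }
    return pd.DataFrame([row])
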