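"""Classification rule, run-level quantification, and the full pipeline."""

import dataclasses
import logging

import numpy as np
import pytest

import cyanovia as cv
from conftest import make_field


def particle(mean_green: float) -> cv.Particle:
    return cv.Particle(1, 200, 50.0, (5.0, 5.0), 150.0, mean_green, False)


@pytest.mark.parametrize(
    "mean_green,expected",
    [(120.0, cv.NONVIABLE), (49.9, cv.VIABLE), (50.0, cv.VIABLE), (50.01, cv.NONVIABLE)],
)
def test_green_mean_rule_with_strict_inequality(mean_green, expected, config):
    assert cv.classify_particle(particle(mean_green), config) == expected


def _run_with_counts(n_viable: int, n_nonviable: int, config: cv.AssayConfig):
    px = np.zeros((4, 4, 3), dtype=np.uint8)
    fld = make_field(px)
    parts = tuple(
        cv.Particle(i + 1, 200, 50.0, (1.0, 1.0), 150.0, 20.0 if i < n_viable else 120.0, False)
        for i in range(n_viable + n_nonviable)
    )
    ps = cv.ParticleSet(field_id="f", particles=parts, thresholds_used=(30, 25))
    return cv.quantify(cv.FieldSet(fields=(fld,), config=config), [ps])


def test_concentration_from_chamber_constants(config):
    """2100 cells over the 0.084 ul imaged volume, diluted 1:2 -> 5e7 cells/ml."""
    res = _run_with_counts(2100, 0, config)
    assert res.concentration_cells_per_ml == pytest.approx(5.0e7)
    assert res.viable_fraction == 1.0


def test_viable_fraction_and_linearity_in_dilution(config):
    res = _run_with_counts(98, 2, config)
    assert res.n_total == 100
    assert res.viable_fraction == pytest.approx(0.98)
    cfg3 = dataclasses.replace(config, dilution_factor=3.0)
    res3 = _run_with_counts(98, 2, cfg3)
    assert res3.concentration_cells_per_ml == pytest.approx(
        res.concentration_cells_per_ml * 1.5
    )


def test_zero_particles_gives_undefined_fraction(config):
    res = _run_with_counts(0, 0, config)
    assert res.n_total == 0
    assert res.viable_fraction is None
    assert res.concentration_cells_per_ml == 0.0


def test_quantify_rejects_zero_fields(config):
    with pytest.raises(ValueError):
        cv.quantify(cv.FieldSet(fields=(), config=config), [])


@pytest.mark.parametrize("n_red,n_green", [(50, 50), (100, 0), (0, 100)])
def test_noise_free_scene_recovers_exact_counts(n_red, n_green):
    spec = cv.SceneSpec(n_red=n_red, n_green=n_green, noise_sigma=0.0, seed=11)
    fld, truth = cv.render_field(spec)
    result, particles = cv.run_assay(cv.FieldSet(fields=(fld,)))
    assert (result.n_viable, result.n_nonviable) == (n_red, n_green)
    assert len(particles) == n_red + n_green


def test_channel_swap_swaps_the_counts():
    """With symmetric red/green renderings, swapping channels swaps classes."""
    spec = cv.SceneSpec(
        n_red=30,
        n_green=10,
        noise_sigma=0.0,
        red_cell_intensity=(150.0, 0.0),
        green_cell_intensity=(150.0, 0.0),
        seed=5,
    )
    fld, _ = cv.render_field(spec)
    res, _ = cv.run_assay(cv.FieldSet(fields=(fld,)))
    swapped_px = fld.pixels[:, :, [1, 0, 2]]
    swapped = make_field(swapped_px, um_per_px=spec.um_per_px, field_id="swapped")
    res_swapped, _ = cv.run_assay(cv.FieldSet(fields=(swapped,)))
    assert (res.n_viable, res.n_nonviable) == (30, 10)
    assert (res_swapped.n_viable, res_swapped.n_nonviable) == (10, 30)


def test_all_black_field_counts_nothing_and_warns(caplog):
    fld = make_field(np.zeros((64, 64, 3), dtype=np.uint8))
    with caplog.at_level(logging.WARNING, logger="cyanovia.viability"):
        result, particles = cv.run_assay(cv.FieldSet(fields=(fld,)))
    assert result.n_total == 0
    assert len(particles) == 0
    assert any("degenerate" in rec.message for rec in caplog.records)


def test_one_empty_channel_still_processes_the_other():
    """A fully viable culture has an empty green channel but must still count."""
    # off-channel rendered at the background level -> green channel is uniform
    spec = cv.SceneSpec(n_red=20, n_green=0, noise_sigma=0.0, off_channel_intensity=8.0, seed=3)
    fld, _ = cv.render_field(spec)
    assert len(np.unique(fld.green)) == 1  # degenerate green histogram
    res, _ = cv.run_assay(cv.FieldSet(fields=(fld,)))
    assert (res.n_viable, res.n_nonviable) == (20, 0)


def test_pipeline_is_deterministic():
    spec = cv.SceneSpec(n_red=25, n_green=25, seed=42)
    fld, _ = cv.render_field(spec)
    run = cv.FieldSet(fields=(fld,))
    r1, df1 = cv.run_assay(run)
    r2, df2 = cv.run_assay(run)
    assert r1.per_field_counts.equals(r2.per_field_counts)
    assert df1.equals(df2)


def test_summary_frame_layout():
    spec = cv.SceneSpec(n_red=5, n_green=5, seed=9)
    fld, _ = cv.render_field(spec)
    run = cv.FieldSet(fields=(fld,))
    result, _ = cv.run_assay(run)
    df = cv.summary_frame("demo", run, result)
    assert list(df.columns) == [
        "run_id",
        "n_fields",
        "n_viable",
        "n_nonviable",
        "viable_percent",
        "concentration_cells_per_ml",
        "t_red_per_field",
        "t_green_per_field",
        "config",
    ]
    assert df.loc[0, "n_viable"] + df.loc[0, "n_nonviable"] == result.n_total
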