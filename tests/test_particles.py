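"""Particle registration, measurement, and the 35 um^2 artifact filter."""

import dataclasses

import numpy as np
import pytest

import cyanovia as cv
from conftest import make_field


def field_with_mask(mask: np.ndarray, green_value: int = 120, um_per_px: float = 0.5):
    """Field whose green channel carries ``green_value`` under the mask."""
    px = np.zeros((*mask.shape, 3), dtype=np.uint8)
    px[:, :, 1][mask] = green_value
    return make_field(px, um_per_px=um_per_px)


def test_combine_masks_is_or_with_identity_and_idempotence():
    a = np.array([[True, False]])
    b = np.array([[False, True]])
    np.testing.assert_array_equal(cv.combine_masks(a, b), [[True, True]])
    np.testing.assert_array_equal(cv.combine_masks(a, np.zeros_like(a)), a)
    np.testing.assert_array_equal(cv.combine_masks(a, a), a)
    with pytest.raises(ValueError, match="dimensions"):
        cv.combine_masks(a, np.array([[True]]))


def test_two_disjoint_squares_register_separately(config):
    mask = np.zeros((12, 12), dtype=bool)
    mask[1:4, 1:4] = True
    mask[7:10, 7:10] = True
    ps = cv.register_particles(mask, field_with_mask(mask), config)
    assert len(ps) == 2
    assert sorted(p.area_px for p in ps.particles) == [9, 9]
    assert all(p.area_um2 == 9 * 0.25 for p in ps.particles)


@pytest.mark.parametrize("connectivity,expected", [(8, 1), (4, 2)])
def test_diagonal_touch_follows_connectivity(connectivity, expected):
    mask = np.zeros((6, 6), dtype=bool)
    mask[2, 2] = True
    mask[3, 3] = True
    cfg = cv.AssayConfig(connectivity=connectivity)
    ps = cv.register_particles(mask, field_with_mask(mask), cfg)
    assert len(ps) == expected


def test_mean_intensity_measured_on_raw_channels(config):
    mask = np.zeros((8, 8), dtype=bool)
    mask[2:5, 2:5] = True
    fld = field_with_mask(mask, green_value=120)
    ps = cv.register_particles(mask, fld, config)
    assert ps.particles[0].mean_green == 120.0
    assert ps.particles[0].mean_red == 0.0
    assert ps.particles[0].centroid == (3.0, 3.0)


def test_edge_particles_flagged_and_optionally_dropped():
    mask = np.zeros((10, 10), dtype=bool)
    mask[0, 0:3] = True  # touches border
    mask[5:8, 5:8] = True  # interior
    fld = field_with_mask(mask)
    ps = cv.register_particles(mask, fld, cv.AssayConfig(include_edge_particles=True))
    assert sorted(p.touches_edge for p in ps.particles) == [False, True]
    ps2 = cv.register_particles(mask, fld, cv.AssayConfig(include_edge_particles=False))
    assert len(ps2) == 1 and not ps2.particles[0].touches_edge


def test_area_filter_boundary_at_printed_cutoff(config):
    """At 0.5 um/px a pixel is 0.25 um^2: 139 px = 34.75 um^2 is dropped,
    140 px = 35.0 um^2 exactly is retained (strict 'smaller than')."""
    small = np.zeros((40, 40), dtype=bool)
    small[1:8, 1:21] = True
    small[1, 1] = False  # 7x20 - 1 = 139 px = 34.75 um^2
    ps = cv.filter_artifacts(cv.register_particles(small, field_with_mask(small), config), config)
    assert len(ps) == 0
    exact = np.zeros((40, 40), dtype=bool)
    exact[1:8, 1:21] = True  # 140 px = 35.0 um^2
    ps = cv.filter_artifacts(cv.register_particles(exact, field_with_mask(exact), config), config)
    assert len(ps) == 1 and ps.particles[0].area_um2 == 35.0


def test_filter_is_idempotent_and_preserves_ids(config):
    mask = np.zeros((30, 60), dtype=bool)
    mask[1:8, 1:21] = True  # kept, 140 px
    mask[15:17, 1:3] = True  # 4 px speck, dropped
    mask[1:8, 30:50] = True  # kept
    ps = cv.register_particles(mask, field_with_mask(mask), config)
    once = cv.filter_artifacts(ps, config)
    twice = cv.filter_artifacts(once, config)
    assert once == twice
    assert [p.particle_id for p in once.particles] == sorted(
        p.particle_id for p in once.particles
    )


def test_pixel_conservation_before_filtering(config, rng):
    mask = rng.random((64, 64)) > 0.7
    ps = cv.register_particles(mask, field_with_mask(mask), config)
    assert sum(p.area_px for p in ps.particles) == int(mask.sum())


def test_empty_mask_yields_empty_set(config):
    mask = np.zeros((10, 10), dtype=bool)
    ps = cv.register_particles(mask, field_with_mask(mask), config)
    assert len(ps) == 0
    assert len(cv.filter_artifacts(ps, config)) == 0


def test_duplicate_particle_ids_rejected():
    p = cv.Particle(1, 9, 2.25, (0.0, 0.0), 0.0, 0.0, False)
    with pytest.raises(ValueError, match="unique"):
        cv.ParticleSet(field_id="f", particles=(p, dataclasses.replace(p)))
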