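"""Registration and projection contracts."""

import numpy as np
import pytest

from rhocta import (
    HistologyStack,
    max_intensity_project,
    register_sections,
    render_histology_stack,
    segment_vessels,
)


def test_known_jitter_recovered_within_one_pixel(small_network):
    for seed in range(3):
        stack = render_histology_stack(small_network, jitter_px=5, seed=seed)
        registered = register_sections(stack)
        # the correction undoes the applied offset
        err = np.abs(registered.applied_shifts + stack.true_offsets)
        assert err.max() <= 1


def test_already_aligned_stack_has_zero_shifts(small_network):
    stack = render_histology_stack(small_network, jitter_px=0, seed=0)
    registered = register_sections(stack)
    assert np.all(registered.applied_shifts == 0)


def test_two_identical_sections_register_with_zero_shift():
    rng = np.random.default_rng(0)
    section = rng.uniform(size=(64, 64))
    stack = HistologyStack(np.stack([section, section]), np.array([40.0, 440.0]), 6.5)
    registered = register_sections(stack)
    assert np.all(registered.applied_shifts == 0)


def test_registering_a_registered_stack_is_a_fixed_point(small_network):
    stack = render_histology_stack(small_network, jitter_px=4, seed=2)
    once = register_sections(stack)
    twice = register_sections(once)
    assert np.all(twice.applied_shifts == 0)


def test_flat_section_warns_and_gets_zero_shift():
    rng = np.random.default_rng(1)
    sections = np.stack([rng.uniform(size=(32, 32)), np.full((32, 32), 0.5)])
    stack = HistologyStack(sections, np.array([40.0, 440.0]), 6.5)
    with pytest.warns(UserWarning, match="flat"):
        registered = register_sections(stack)
    assert np.all(registered.applied_shifts == 0)


def test_single_section_stack_cannot_be_registered():
    stack = HistologyStack(np.zeros((1, 8, 8)), np.array([40.0]), 6.5)
    with pytest.raises(ValueError, match="2 sections"):
        register_sections(stack)


# -- projection -------------------------------------------------------------


def test_projection_of_one_section_is_that_section():
    section = np.random.default_rng(3).uniform(size=(16, 16))
    stack = HistologyStack(section[None], np.array([40.0]), 6.5)
    assert np.array_equal(max_intensity_project(stack).pixels, section)


def test_projection_contains_disjoint_bright_vessels():
    a = np.zeros((16, 16))
    b = np.zeros((16, 16))
    a[2, 2] = 1.0
    b[10, 10] = 1.0
    stack = HistologyStack(np.stack([a, b]), np.array([40.0, 440.0]), 6.5)
    proj = max_intensity_project(stack)
    assert proj.pixels[2, 2] == 1.0 and proj.pixels[10, 10] == 1.0
    assert proj.state == "histology"


def test_projection_is_permutation_invariant(small_network):
    stack = render_histology_stack(small_network, jitter_px=3, seed=5)
    reversed_stack = HistologyStack(
        stack.sections[::-1].copy(), stack.depths_um, stack.pixel_pitch_um
    )
    a = max_intensity_project(stack).pixels
    b = max_intensity_project(reversed_stack).pixels
    assert np.array_equal(a, b)


def test_registered_projection_segments_against_full_network(small_network):
    stack = render_histology_stack(small_network, jitter_px=4, shrinkage=1.0, seed=7)
    proj = max_intensity_project(register_sections(stack))
    mask = segment_vessels(proj)
    from rhocta.synthetic import rasterize_segments

    truth = rasterize_segments(
        small_network.segments, small_network.field_size_um, stack.pixel_pitch_um
    )
    inter = np.logical_and(mask.mask, truth).sum()
    dice = 2.0 * inter / (mask.mask.sum() + truth.sum())
    assert dice >= 0.8
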