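"""Generator contracts: determinism, truth bookkeeping, artifact models."""

import numpy as np
import pytest

from rhocta import (
    ArtifactParams,
    BranchingParams,
    add_artifacts,
    generate_network,
    render_enface,
    render_histology_stack,
)
from rhocta.synthetic import rasterize_segments

from conftest import SMALL_FIELD_MM, SEED


def test_same_seed_reproduces_identical_network(small_network):
    again = generate_network(field_size_mm=SMALL_FIELD_MM, target_density=0.25, seed=SEED)
    assert len(again.segments) == len(small_network.segments)
    for a, b in zip(again.segments, small_network.segments):
        assert a == b


def test_truth_centerline_equals_sum_of_segment_lengths(small_network):
    for state in ("baseline", "hyperemia"):
        total = sum(s.length_um for s in small_network._selected(state))
        assert small_network.centerline_length_um(state) == pytest.approx(total, rel=1e-9)


def test_hyperemia_truth_is_superset_of_baseline(small_network):
    _, tb = render_enface(small_network, "baseline")
    _, th = render_enface(small_network, "hyperemia")
    assert th.area_fraction >= tb.area_fraction
    assert th.centerline_length_per_area >= tb.centerline_length_per_area


def test_compressed_render_has_no_vessel_pixels(compressed_render):
    image, truth = compressed_render
    assert truth.area_fraction == 0.0
    assert truth.branch_count == 0
    # only the uniform background remains
    assert np.ptp(image.pixels) == 0.0


def test_single_segment_network_has_no_branch_points():
    net = generate_network(
        field_size_mm=SMALL_FIELD_MM,
        target_density=0.25,
        branching_params=BranchingParams(max_segments=1),
        seed=0,
    )
    assert len(net.segments) == 1
    assert net.branch_count("hyperemia") == 0


def test_small_field_truth_density_within_tolerance(small_network):
    truth = small_network.compute_truth("hyperemia", dilation_factor=1.0)
    assert 0.25 * 0.8 <= truth.area_fraction <= 0.25 * 1.2


@pytest.mark.slow
def test_full_field_truth_density_within_tolerance():
    # the 6.006 mm (924 px) field used by the acquisition protocol;
    # generation is O(segments^2) so this is the suite's slowest test
    net = generate_network(field_size_mm=6.006, target_density=0.25, seed=1)
    truth = net.compute_truth("hyperemia", dilation_factor=1.0)
    assert 0.20 <= truth.area_fraction <= 0.30


def test_all_perfused_undilated_states_are_identical():
    net = generate_network(
        field_size_mm=SMALL_FIELD_MM,
        target_density=0.25,
        branching_params=BranchingParams(unperfused_terminal_frac=0.0),
        seed=3,
    )
    _, tb = render_enface(net, "baseline", dilation_factor=1.0)
    _, th = render_enface(net, "hyperemia", dilation_factor=1.0)
    assert tb == th


def test_incommensurate_pixel_pitch_is_rejected(small_network):
    with pytest.raises(ValueError, match="pitch"):
        render_enface(small_network, "baseline", pixel_pitch_um=7.0)


def test_network_json_roundtrip(tmp_path, small_network):
    p = tmp_path / "net.json"
    small_network.truth_metrics["baseline"] = small_network.compute_truth("baseline")
    small_network.to_json(p)
    back = type(small_network).from_json(p)
    assert back.segments == small_network.segments
    assert back.truth_metrics == small_network.truth_metrics


# -- artifacts --------------------------------------------------------------


def test_artifact_free_params_are_identity(baseline_render):
    image, _ = baseline_render
    out = add_artifacts(image, ArtifactParams(speckle_contrast=0.0, stripe_amplitude=0.0))
    assert np.array_equal(out.pixels, image.pixels)


def test_stripe_injection_varies_column_means(baseline_render):
    image, _ = baseline_render
    flat = image.with_pixels(np.full_like(image.pixels, 0.5))
    striped = add_artifacts(flat, ArtifactParams(speckle_contrast=0.0, stripe_amplitude=0.3))
    col_means = striped.pixels.mean(axis=0)
    assert col_means.std() / col_means.mean() > 0.0
    # stripes are constant within a column
    assert np.allclose(striped.pixels.std(axis=0), 0.0)


def test_artifacts_deterministic_under_seed(noisy_baseline, baseline_render):
    image, _ = baseline_render
    again = add_artifacts(image, ArtifactParams(seed=SEED + 100))
    assert np.array_equal(again.pixels, noisy_baseline.pixels)


def test_speckle_is_multiplicative_on_background(compressed_render):
    image, _ = compressed_render
    out = add_artifacts(image, ArtifactParams(speckle_contrast=0.5, stripe_amplitude=0.0, seed=0))
    # background 0.05 x unit-mean speckle stays near 0.05 on average
    assert out.pixels.mean() == pytest.approx(0.05, rel=0.05)


# -- histology stacks -------------------------------------------------------


def test_zero_jitter_full_shrinkage_sections_identical(small_network):
    stack = render_histology_stack(small_network, jitter_px=0, shrinkage=1.0, seed=0)
    for i in range(1, stack.n_sections):
        assert np.array_equal(stack.sections[i], stack.sections[0])
    assert np.all(stack.true_offsets == 0)


def test_section_depths_span_range_with_even_spacing(small_network):
    stack = render_histology_stack(small_network, n_sections=10, seed=0)
    assert stack.depths_um[0] == 40.0 and stack.depths_um[-1] == 440.0
    assert np.allclose(np.diff(stack.depths_um), (440.0 - 40.0) / 9)


def test_supplied_offsets_recorded_verbatim(small_network):
    offsets = [(0, 0), (3, -2)] + [(0, 0)] * 8
    stack = render_histology_stack(small_network, offsets=offsets, seed=0)
    assert tuple(stack.true_offsets[1]) == (3, -2)


def test_histology_draws_all_segments_regardless_of_perfusion(small_network):
    stack = render_histology_stack(small_network, jitter_px=0, shrinkage=1.0, seed=0)
    full = rasterize_segments(
        small_network.segments, small_network.field_size_um, stack.pixel_pitch_um
    )
    assert np.array_equal(stack.sections[0] > 0.5, full)
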