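"""Generator invariants: geometry matches closed forms, kinetics follow the
growth/conversion model, and everything is bit-deterministic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonypat import (
    BACKGROUND,
    CENTRAL_CORE,
    CLASS_NAMES,
    CORE_PERIPHERY,
    EDGE,
    ColonySpec,
    CountTableSpec,
    SceneSpec,
    generate_count_table,
    mask_timeseries,
    render_frame,
    render_mask,
    render_timeseries,
)


def one_colony_scene(diameter_um=400.0, fractions=(0.6, 0.25, 0.15), **kw):
    return SceneSpec(
        image_height_px=512,
        image_width_px=512,
        colonies=(
            ColonySpec(
                center_rc=(256.0, 256.0),
                initial_diameter_um=diameter_um,
                zone_fractions=fractions,
            ),
        ),
        **kw,
    )


def test_empty_scene_is_pure_background():
    spec = SceneSpec(image_height_px=256, image_width_px=256)
    image, truth = render_frame(spec, 0.0, seed=0)
    assert np.all(truth.mask == BACKGROUND)
    assert truth.colonies.empty
    assert image.shape == (256, 256)
    assert 0.0 <= image.min() and image.max() <= 1.0


def test_zone_areas_match_analytic_discs():
    # diameter 400 um at 2 um/px -> outer radius 100 px; zone radii at
    # 0.6 and 0.85 of that; pixelated areas within 2% of the closed form
    spec = one_colony_scene()
    truth = render_mask(spec, 0.0)
    r_outer = 100.0
    r_core = 0.6 * r_outer
    r_mid = 0.85 * r_outer
    expect = {
        CENTRAL_CORE: np.pi * r_core**2,
        CORE_PERIPHERY: np.pi * (r_mid**2 - r_core**2),
        EDGE: np.pi * (r_outer**2 - r_mid**2),
    }
    for code, area in expect.items():
        n_px = np.count_nonzero(truth.mask == code)
        assert abs(n_px - area) / area < 0.02
    # truth table areas are exactly pixel counts times the pixel area
    row = truth.colonies.iloc[0]
    assert row["core_um2"] == np.count_nonzero(truth.mask == CENTRAL_CORE) * 4.0
    assert row["edge_um2"] == np.count_nonzero(truth.mask == EDGE) * 4.0


def test_render_is_bit_deterministic():
    spec = one_colony_scene()
    img1, t1 = render_frame(spec, 5.0, seed=42)
    img2, t2 = render_frame(spec, 5.0, seed=42)
    assert np.array_equal(img1, img2)
    assert np.array_equal(t1.mask, t2.mask)
    img3, _ = render_frame(spec, 5.0, seed=43)
    assert not np.array_equal(img1, img3)


def test_mask_labels_confined_to_four_classes():
    spec = one_colony_scene()
    truth = render_mask(spec, 10.0)
    assert set(np.unique(truth.mask)) <= {BACKGROUND, CENTRAL_CORE, CORE_PERIPHERY, EDGE}


def test_out_of_bounds_colony_names_the_colony():
    spec = SceneSpec(
        image_height_px=256,
        image_width_px=256,
        colonies=(
            ColonySpec(center_rc=(128.0, 128.0), initial_diameter_um=200.0),
            ColonySpec(center_rc=(20.0, 128.0), initial_diameter_um=200.0),
        ),
    )
    with pytest.raises(ValueError, match="colony 1"):
        render_mask(spec, 0.0)


def test_overlapping_colonies_after_growth_error():
    spec = SceneSpec(
        image_height_px=512,
        image_width_px=512,
        colonies=(
            ColonySpec(center_rc=(256.0, 150.0), initial_diameter_um=380.0),
            ColonySpec(center_rc=(256.0, 362.0), initial_diameter_um=380.0),
        ),
        growth_rate_um_per_h=10.0,
    )
    render_mask(spec, 0.0)  # fine initially
    with pytest.raises(ValueError, match="overlap"):
        mask_timeseries(spec, n_frames=10)


def test_static_scene_gives_identical_masks():
    spec = one_colony_scene(growth_rate_um_per_h=0.0)
    frames, table = render_timeseries(spec, n_frames=3, seed=3)
    masks = [t.mask for _, t in frames]
    assert np.array_equal(masks[0], masks[1]) and np.array_equal(masks[0], masks[2])
    assert len(table) == 3


def test_small_colony_converts_fully_large_retains_core():
    common = dict(
        growth_rate_um_per_h=0.0,
        differentiation_onset_h=1.0,
        edge_conversion_rate_per_h=0.05,
        core_retention_diameter_um=400.0,
        frame_interval_h=2.0,
    )
    small = one_colony_scene(diameter_um=300.0, **common)
    truths, _ = mask_timeseries(small, n_frames=12)
    final = truths[-1].mask
    assert np.count_nonzero(final == CENTRAL_CORE) == 0
    assert np.count_nonzero(final == CORE_PERIPHERY) == 0
    assert np.count_nonzero(final == EDGE) > 0

    large = one_colony_scene(diameter_um=500.0, **common)
    truths, _ = mask_timeseries(large, n_frames=12)
    for truth in truths:
        assert np.count_nonzero(truth.mask == CENTRAL_CORE) > 0


def test_edge_area_nondecreasing_after_onset():
    spec = one_colony_scene(
        diameter_um=420.0,
        growth_rate_um_per_h=0.0,
        differentiation_onset_h=2.0,
        edge_conversion_rate_per_h=0.04,
    )
    _, table = mask_timeseries(spec, n_frames=20)
    after = table[table["time_h"] >= 2.0]["edge_um2"].to_numpy()
    assert np.all(np.diff(after) >= 0)


@given(
    f_core=st.floats(0.2, 0.7),
    f_peri=st.floats(0.05, 0.25),
    diameter=st.floats(150.0, 450.0),
)
@settings(max_examples=20, deadline=None, derandomize=True)
def test_truth_table_consistent_with_mask(f_core, f_peri, diameter):
    f_edge = 1.0 - f_core - f_peri
    spec = one_colony_scene(diameter_um=diameter, fractions=(f_core, f_peri, f_edge))
    truth = render_mask(spec, 0.0)
    row = truth.colonies.iloc[0]
    for code, col in [
        (CENTRAL_CORE, "core_um2"),
        (CORE_PERIPHERY, "periphery_um2"),
        (EDGE, "edge_um2"),
    ]:
        assert row[col] == np.count_nonzero(truth.mask == code) * spec.um_per_px**2


def test_count_table_noiseless_is_exactly_linear():
    spec = CountTableSpec(n_samples=30, noise_sd_cells=0.0)
    table = generate_count_table(spec, seed=5)
    expected = (
        spec.beta0
        + spec.beta_core * table["core_pct"]
        + spec.beta_periphery * table["periphery_pct"]
        + spec.beta_edge * table["edge_pct"]
    )
    assert np.allclose(table["cell_count"], expected)


def test_count_table_zero_coverage_gives_intercept():
    spec = CountTableSpec(
        n_samples=10,
        noise_sd_cells=0.0,
        core_range=(0, 0),
        periphery_range=(0, 0),
        edge_range=(0, 0),
    )
    table = generate_count_table(spec, seed=1)
    assert np.allclose(table["cell_count"], spec.beta0)


def test_count_table_clips_negative_counts(caplog):
    spec = CountTableSpec(
        n_samples=50, beta0=0.0, noise_sd_cells=1e5,
        core_range=(0, 0), periphery_range=(0, 0), edge_range=(0, 0),
    )
    with caplog.at_level("WARNING", logger="colonypat.synthetic"):
        table = generate_count_table(spec, seed=2)
    assert (table["cell_count"] >= 0).all()
    assert any("clipped" in r.message for r in caplog.records)


def test_count_table_deterministic():
    spec = CountTableSpec(n_samples=25)
    pd.testing.assert_frame_equal(
        generate_count_table(spec, seed=9), generate_count_table(spec, seed=9)
    )


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        ColonySpec(center_rc=(0, 0), initial_diameter_um=100.0, zone_fractions=(0.5, 0.4, 0.3))
    with pytest.raises(ValueError):
        SceneSpec(image_height_px=100, image_width_px=100, frame_interval_h=0.0)
    with pytest.raises(ValueError):
        CountTableSpec(n_samples=1)
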