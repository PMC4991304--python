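"""Colony segmentation, tracking, size-response and trigger logic on
constructed label maps and generator truth."""

import numpy as np
import pytest

from colonypat import (
    ColonyRecord,
    ColonySpec,
    SceneSpec,
    render_frame,
    classify_image,
    response_rate,
    segment_colonies,
    size_response,
    track_colonies,
    trigger_on_mean_diameter,
)
from colonypat.classify import TileLabelMap, tile_grid
from colonypat.colonies import ColonyTrack


def make_labelmap(codes: np.ndarray, frame_index=0) -> TileLabelMap:
    """Build a TileLabelMap directly from an integer code grid."""
    names = np.array(["background", "central_core", "core_periphery", "edge"])
    labels = names[codes]
    grid = tile_grid(codes.shape[0] * 64, codes.shape[1] * 64)
    return TileLabelMap(
        grid=grid, labels=labels, scores=np.zeros(codes.shape), frame_index=frame_index
    )


def test_background_map_gives_no_colonies():
    lm = make_labelmap(np.zeros((6, 6), dtype=int))
    assert segment_colonies(lm, um_per_px=2.0) == []


def test_two_disjoint_blocks_segment_separately():
    codes = np.zeros((10, 10), dtype=int)
    codes[1:4, 1:4] = 1
    codes[6:9, 6:9] = 3
    records = segment_colonies(make_labelmap(codes), um_per_px=2.0)
    assert len(records) == 2
    assert sorted(r.tile_count for r in records) == [9, 9]
    tile_um = 64 * 2.0
    for r in records:
        assert r.area_um2 == r.tile_count * tile_um**2
        assert r.diameter_um == pytest.approx(2 * np.sqrt(r.area_um2 / np.pi))
        assert sum(r.composition_pct.values()) == pytest.approx(100.0)


def test_single_tiles_discarded_as_debris():
    codes = np.zeros((6, 6), dtype=int)
    codes[0, 0] = 3  # lone tile
    codes[3, 3] = 1
    codes[3, 4] = 1
    records = segment_colonies(make_labelmap(codes), um_per_px=2.0)
    assert len(records) == 1
    assert records[0].tile_count == 2


def test_diagonal_tiles_not_connected():
    codes = np.zeros((6, 6), dtype=int)
    codes[1, 1] = codes[2, 2] = 1  # touch only diagonally: 4-connectivity splits
    records = segment_colonies(make_labelmap(codes), um_per_px=2.0, min_tiles=1)
    assert len(records) == 2


def test_segmentation_matches_generator_truth(small_library):
    spec = SceneSpec(
        image_height_px=1024,
        image_width_px=1024,
        colonies=(
            ColonySpec(center_rc=(280.0, 280.0), initial_diameter_um=500.0),
            ColonySpec(center_rc=(720.0, 720.0), initial_diameter_um=350.0),
        ),
    )
    image, truth = render_frame(spec, 0.0, seed=21)
    labelmap, _ = classify_image(image, small_library)
    records = segment_colonies(labelmap, spec.um_per_px)
    assert len(records) == 2
    measured = sorted(r.diameter_um for r in records)
    for got, want in zip(measured, [350.0, 500.0]):
        assert abs(got - want) <= 64 * spec.um_per_px  # within one tile edge


def _record(cid, frame, t, row, col, n_tiles=4, edge=0.0):
    tile_um = 64 * 2.0
    area = n_tiles * tile_um**2
    return ColonyRecord(
        colony_id=cid,
        frame_index=frame,
        time_h=t,
        tile_count=n_tiles,
        area_um2=area,
        diameter_um=2 * np.sqrt(area / np.pi),
        composition_pct={
            "background": 0.0,
            "central_core": 100.0 - edge,
            "core_periphery": 0.0,
            "edge": edge,
        },
        centroid_tiles=(row, col),
    )


def test_static_tracking_one_track_per_colony():
    frames = [
        [_record(0, f, f * 0.5, 2.0, 2.0), _record(1, f, f * 0.5, 8.0, 8.0)]
        for f in range(5)
    ]
    tracks = track_colonies(frames)
    assert len(tracks) == 2
    assert all(len(t.records) == 5 for t in tracks)


def test_tracking_permutation_invariant():
    frames = [
        [_record(0, f, f * 0.5, 2.0, 2.0), _record(1, f, f * 0.5, 8.0, 8.0)]
        for f in range(4)
    ]
    swapped = [list(reversed(frame)) for frame in frames]
    t1 = track_colonies(frames)
    t2 = track_colonies(swapped)
    c1 = sorted(tuple(r.centroid_tiles for r in t.records) for t in t1)
    c2 = sorted(tuple(r.centroid_tiles for r in t.records) for t in t2)
    assert c1 == c2


def test_disappearing_colony_track_ends():
    frames = [
        [_record(0, 0, 0.0, 2.0, 2.0), _record(1, 0, 0.0, 8.0, 8.0)],
        [_record(0, 1, 0.5, 2.0, 2.0)],
        [_record(0, 2, 1.0, 2.0, 2.0), _record(1, 2, 1.0, 8.0, 8.0)],
    ]
    tracks = track_colonies(frames)
    lengths = sorted(len(t.records) for t in tracks)
    assert lengths == [1, 1, 3]  # the returning colony starts a new track


def test_growing_colonies_keep_their_tracks(small_library):
    spec = SceneSpec(
        image_height_px=768,
        image_width_px=768,
        colonies=(ColonySpec(center_rc=(384.0, 384.0), initial_diameter_um=400.0),),
        growth_rate_um_per_h=20.0,
        frame_interval_h=4.0,
    )
    frames = []
    for i in range(4):
        image, _ = render_frame(spec, i * 4.0, seed=30 + i)
        lm, _ = classify_image(image, small_library)
        frames.append(segment_colonies(lm, spec.um_per_px, time_h=i * 4.0))
    tracks = track_colonies(frames)
    assert len(tracks) == 1
    diam = [r.diameter_um for r in tracks[0].records]
    assert all(b >= a for a, b in zip(diam, diam[1:]))


def test_size_response_requires_three_tracks():
    tracks = [
        ColonyTrack(0, [_record(0, 0, 0.0, 2, 2), _record(0, 1, 10.0, 2, 2)]),
        ColonyTrack(1, [_record(1, 0, 0.0, 8, 8), _record(1, 1, 10.0, 8, 8)]),
    ]
    with pytest.raises(ValueError, match="3 tracks"):
        size_response(tracks, 0.0, 10.0)


def test_size_response_zero_variance_reported_absent():
    tracks = [
        ColonyTrack(i, [_record(i, 0, 0.0, 2 * i, 2), _record(i, 1, 10.0, 2 * i, 2)])
        for i in range(4)
    ]
    with pytest.warns(UserWarning, match="zero variance"):
        res = size_response(tracks, 0.0, 10.0)
    assert res.pearson_r is None


def test_trigger_first_crossing():
    def frame(t, d_um):
        rec = _record(0, 0, t, 2, 2)
        rec.diameter_um = d_um
        return [rec]

    frames = [frame(0.0, 250.0), frame(0.5, 290.0), frame(1.0, 310.0)]
    res = trigger_on_mean_diameter(frames, 300.0)
    assert res.trigger_time_h == 1.0
    res = trigger_on_mean_diameter(frames, 750.0)
    assert res.trigger_time_h is None
    with pytest.raises(ValueError):
        trigger_on_mean_diameter([], 300.0)


def test_trigger_linear_growth_closed_form(small_library):
    # growth at 16 um/h from 430 um: 500 um is crossed at t = 4.375 h;
    # tile-resolution measurement should trigger within one 2-h frame
    spec = SceneSpec(
        image_height_px=768,
        image_width_px=768,
        colonies=(ColonySpec(center_rc=(384.0, 384.0), initial_diameter_um=430.0),),
        growth_rate_um_per_h=16.0,
        frame_interval_h=2.0,
    )
    frames = []
    for i in range(8):
        image, _ = render_frame(spec, i * 2.0, seed=40 + i)
        lm, _ = classify_image(image, small_library)
        frames.append(segment_colonies(lm, spec.um_per_px, time_h=i * 2.0))
    res = trigger_on_mean_diameter(frames, 500.0)
    assert res.trigger_time_h is not None
    expected = (500.0 - 430.0) / 16.0
    assert abs(res.trigger_time_h - expected) <= 64 * spec.um_per_px / 16.0 + 2.0


def test_response_rate_closed_forms():
    t = np.arange(0.0, 5.0, 0.5)
    assert response_rate(t, 3.0 * t + 7.0, 0.0, 5.0) == pytest.approx(3.0)
    assert response_rate(t, np.full_like(t, 9.0), 0.0, 5.0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        response_rate(t[:2], t[:2], 0.0, 5.0)
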