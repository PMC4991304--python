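"""Standard synthetic study conditions.

The monitoring, precision, size-response and counting analyses in this
package are exercised on fixed synthetic populations defined here, so
that the analysis drivers, the test suite and the acceptance script all
run the same conditions.  Sizes follow the real experimental designs
they emulate (36 fields of view per timepoint for separation monitoring,
400-image pools for precision curves, colony populations spanning the
core-retention threshold) at desk scale.
"""

from __future__ import annotations

import numpy as np

from .classify import classify_image
from .colonies import segment_colonies, track_colonies, trigger_on_mean_diameter
from .synthetic import (
    ColonySpec,
    SceneSpec,
    mask_coverage,
    render_frame,
    render_mask,
)


def _child_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Differentiation time course: 20 multi-colony fields spanning 0-28.5 h of
# edge conversion (the population coverage recovery is validated on).

COURSE_N_SCENES = 20
_COURSE_CENTERS = ((320, 320), (320, 960), (960, 320), (960, 960))


def differentiation_course(seed: int, n_scenes: int = COURSE_N_SCENES):
    """Yield (spec, time_h, frame_seed) for a differentiation time course.

    Each scene is a 1280x1280 px field (2.56 mm at 2 um/px) holding four
    colonies of 250-700 um, imaged at a stage stratified over 0-28.5 h
    after a differentiation stimulus.
    """
    times = np.linspace(0.0, 28.5, n_scenes)
    out = []
    for i in range(n_scenes):
        rng = np.random.default_rng(_child_seed(seed, 1, i))
        diameters = rng.uniform(250.0, 700.0, len(_COURSE_CENTERS))
        colonies = tuple(
            ColonySpec(
                center_rc=(cy + rng.uniform(-25, 25), cx + rng.uniform(-25, 25)),
                initial_diameter_um=float(d),
            )
            for (cy, cx), d in zip(_COURSE_CENTERS, diameters)
        )
        spec = SceneSpec(
            image_height_px=1280,
            image_width_px=1280,
            colonies=colonies,
            differentiation_onset_h=0.0,
            growth_rate_um_per_h=0.0,
        )
        out.append((spec, float(times[i]), _child_seed(seed, 2, i)))
    return out


# ---------------------------------------------------------------------------
# Random fields of view: one colony per 256x256 px field, emulating the
# random-position imaging used for coverage precision and separation
# monitoring.  Colony size and placement vary field to field.


def field_of_view_spec(
    rng: np.random.Generator, differentiation_onset_h: float | None = None
) -> SceneSpec:
    diameter = float(rng.uniform(120.0, 260.0))
    cy = 128.0 + float(rng.uniform(-20, 20))
    cx = 128.0 + float(rng.uniform(-20, 20))
    return SceneSpec(
        image_height_px=256,
        image_width_px=256,
        colonies=(ColonySpec(center_rc=(cy, cx), initial_diameter_um=diameter),),
        differentiation_onset_h=differentiation_onset_h,
    )


def coverage_pool(n_images: int, seed: int, time_h: float = 0.0) -> np.ndarray:
    """Edge coverage (%) of ``n_images`` independent fields at one time.

    Mask-derived (exact) coverage; the values are iid across fields, so
    the pool is suitable for SEM-vs-sample-size resampling.
    """
    values = np.empty(n_images)
    for i in range(n_images):
        rng = np.random.default_rng(_child_seed(seed, 3, i))
        truth = render_mask(field_of_view_spec(rng), time_h)
        values[i] = mask_coverage(truth.mask)["edge"]
    return values


MONITORING_N_FOVS = 36  # image sample size per timepoint
MONITORING_N_FRAMES = 24  # 12 h at the 30-min imaging interval
MONITORING_ONSET_H = 3.0


def monitoring_series(
    seed: int,
    n_fovs: int = MONITORING_N_FOVS,
    n_frames: int = MONITORING_N_FRAMES,
    onset_h: float = MONITORING_ONSET_H,
):
    """Control vs differentiation edge-coverage series over shared times.

    Returns (times_h, control, treated), the latter two of shape
    (n_frames, n_fovs) with mask-derived per-field edge coverage.  The
    treated arm receives the differentiation stimulus at ``onset_h``.
    At every timepoint each arm images ``n_fovs`` freshly sampled random
    fields of the culture, so per-image values are independent across
    frames (random-position sampling, not fixed stage positions).
    """
    times = np.arange(n_frames) * 0.5
    control = np.empty((n_frames, n_fovs))
    treated = np.empty((n_frames, n_fovs))
    for i, t in enumerate(times):
        for j in range(n_fovs):
            rng = np.random.default_rng(_child_seed(seed, 4, i, j))
            spec_c = field_of_view_spec(rng)
            rng = np.random.default_rng(_child_seed(seed, 5, i, j))
            spec_t = field_of_view_spec(rng, differentiation_onset_h=onset_h)
            control[i, j] = mask_coverage(render_mask(spec_c, float(t)).mask)["edge"]
            treated[i, j] = mask_coverage(render_mask(spec_t, float(t)).mask)["edge"]
    return times, control, treated


# ---------------------------------------------------------------------------
# Colony size-response population: nine colonies stratified across the
# core-retention threshold, differentiated from t=0 and followed to full
# conversion of the sub-threshold colonies.

_POPULATION_CENTERS = tuple(
    (214 + 426 * i, 214 + 426 * j) for i in range(3) for j in range(3)
)
POPULATION_HORIZON_H = 30.0
POPULATION_FRAME_INTERVAL_H = 3.0


def size_response_population(seed: int) -> SceneSpec:
    """A 1280x1280 px field of nine colonies, 260-760 um, under stimulus.

    Diameters are stratified (evenly spaced) so the population straddles
    the 400 um core-retention threshold, and the five largest colonies
    sit at the grid corners and centre so that neighbouring colonies
    always keep a clear background gap of at least two tile widths —
    tile-resolution segmentation then cannot merge them.  The smallest
    colony (260 um, about four tiles) stays above the two-tile debris
    floor throughout.
    """
    rng = np.random.default_rng(_child_seed(seed, 6))
    diameters = np.linspace(260.0, 760.0, len(_POPULATION_CENTERS))
    # grid order is (corner, edge-mid, corner, mid, centre, mid, corner,
    # mid, corner); give corners/centre the large diameters, mids the small
    rank = [8, 0, 7, 1, 4, 2, 6, 3, 5]
    colonies = tuple(
        ColonySpec(
            center_rc=(cy + rng.uniform(-10, 10), cx + rng.uniform(-10, 10)),
            initial_diameter_um=float(diameters[k]),
        )
        for (cy, cx), k in zip(_POPULATION_CENTERS, rank)
    )
    return SceneSpec(
        image_height_px=1280,
        image_width_px=1280,
        colonies=colonies,
        differentiation_onset_h=0.0,
        growth_rate_um_per_h=0.0,
        frame_interval_h=POPULATION_FRAME_INTERVAL_H,
    )


def classified_population_series(spec: SceneSpec, library, seed: int, n_frames: int):
    """Render, classify and segment a population series.

    Returns (frames_of_records, coverage_records): per-frame colony
    records (for tracking) and image-level coverage records.
    """
    frames = []
    coverages = []
    for i in range(n_frames):
        t = i * spec.frame_interval_h
        image, _ = render_frame(spec, t, seed=_child_seed(seed, 7, i))
        labelmap, record = classify_image(image, library, time_h=t, frame_index=i)
        frames.append(segment_colonies(labelmap, spec.um_per_px, time_h=t))
        record.time_h = t
        coverages.append(record)
    return frames, coverages


# ---------------------------------------------------------------------------
# Diameter-triggered differentiation runs: the stimulus is applied when the
# mean colony diameter crosses a specification (small vs large trigger).

_TRIGGER_CENTERS = ((384, 384), (384, 896), (896, 384), (896, 896))
TRIGGER_RESPONSE_WINDOW_H = 16.0


def triggered_run_spec(threshold_um: float, seed: int) -> SceneSpec:
    """Four growing colonies sized so the mean diameter is approaching
    ``threshold_um``; onset is left unset (applied after trigger detection)."""
    rng = np.random.default_rng(_child_seed(seed, 8, int(threshold_um)))
    diameters = threshold_um - 30.0 + rng.uniform(-15.0, 15.0, len(_TRIGGER_CENTERS))
    colonies = tuple(
        ColonySpec(
            center_rc=(cy + rng.uniform(-15, 15), cx + rng.uniform(-15, 15)),
            initial_diameter_um=float(d),
        )
        for (cy, cx), d in zip(_TRIGGER_CENTERS, diameters)
    )
    return SceneSpec(
        image_height_px=1280,
        image_width_px=1280,
        colonies=colonies,
        frame_interval_h=2.0,
    )


def run_triggered_differentiation(
    threshold_um: float,
    library,
    seed: int,
    max_pre_frames: int = 24,
    post_frames: int = 9,
):
    """Grow colonies, trigger the stimulus at ``threshold_um``, follow the
    edge response.

    The growth phase is monitored through the full pipeline
    (classification + segmentation) frame by frame until the measured
    mean colony diameter crosses the threshold — because diameters are
    tile-resolution, the crossing is detected at the measurement
    granularity, exactly as an in-process trigger would fire.  The run
    then continues with the stimulus applied from the trigger time.
    Returns (trigger_result, times_h, edge_of_cells_pct) where the
    response is edge tiles as % of colony (non-background) tiles.
    """
    import dataclasses

    spec = triggered_run_spec(threshold_um, seed)
    frames = []
    for i in range(max_pre_frames):
        t = i * spec.frame_interval_h
        image, _ = render_frame(spec, t, seed=_child_seed(seed, 9, i))
        labelmap, _ = classify_image(image, library, time_h=t, frame_index=i)
        frames.append(segment_colonies(labelmap, spec.um_per_px, time_h=t))
        if np.mean([r.diameter_um for r in frames[-1]]) >= threshold_um:
            break
    trigger = trigger_on_mean_diameter(frames, threshold_um)
    if trigger.trigger_time_h is None:
        raise RuntimeError(
            f"mean diameter never reached {threshold_um} um within "
            f"{max_pre_frames} growth frames"
        )
    stimulated = dataclasses.replace(spec, differentiation_onset_h=trigger.trigger_time_h)
    times = []
    edge_pct = []
    for j in range(post_frames):
        t = trigger.trigger_time_h + j * spec.frame_interval_h
        image, _ = render_frame(stimulated, t, seed=_child_seed(seed, 10, j))
        _, record = classify_image(image, library, time_h=t)
        times.append(t)
        edge_pct.append(record.edge_pct(of_cells=True))
    return trigger, np.asarray(times), np.asarray(edge_pct)
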