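"""Seeded synthetic phase-contrast-like scenes of pluripotent colony cultures.

A cultured pluripotent colony in phase contrast shows three concentric
morphological zones: a dark, dense central core, a morphologically
intermediate core periphery, and low-density spread edge cells, all on a
bright featureless background.  This module renders parametric scenes of
such colonies with per-pixel ground-truth masks, evolves them in time
(growth, and outside-in conversion to edge morphology after a
differentiation stimulus), and generates tabular cell-count data with a
known linear dependence on per-class coverage.  Every output is a
deterministic function of the spec and an integer seed, so downstream
classification and statistics can be validated against exact truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

# Class codes used throughout the package.
BACKGROUND, CENTRAL_CORE, CORE_PERIPHERY, EDGE = 0, 1, 2, 3
CLASS_NAMES = ("background", "central_core", "core_periphery", "edge")
CLASS_IDS = {name: i for i, name in enumerate(CLASS_NAMES)}


@dataclass(frozen=True)
class ClassTexture:
    """Stationary texture for one morphological class.

    mean/sd are grey levels in [0, 1]; granularity_px is the Gaussian
    smoothing scale of the noise field, i.e. the spatial grain size.
    """

    mean: float
    sd: float
    granularity_px: float


# Core darkest and densest (high-contrast grain), edge lightest and
# sparsest (smooth, low contrast), periphery intermediate.  Chosen so the
# four classes are separable by texture but overlap in raw intensity.
DEFAULT_TEXTURES: dict[str, ClassTexture] = {
    "background": ClassTexture(mean=0.62, sd=0.020, granularity_px=1.0),
    "central_core": ClassTexture(mean=0.30, sd=0.090, granularity_px=1.5),
    "core_periphery": ClassTexture(mean=0.44, sd=0.055, granularity_px=2.5),
    "edge": ClassTexture(mean=0.54, sd=0.035, granularity_px=4.0),
}


@dataclass(frozen=True)
class ColonySpec:
    """One colony: centre (row, col) in px, initial diameter in µm, and
    zone-width fractions (core, periphery, edge) that partition the radius."""

    center_rc: tuple[float, float]
    initial_diameter_um: float
    zone_fractions: tuple[float, float, float] = (0.55, 0.30, 0.15)

    def __post_init__(self) -> None:
        if self.initial_diameter_um <= 0:
            raise ValueError("initial_diameter_um must be positive")
        fr = np.asarray(self.zone_fractions, dtype=float)
        if fr.shape != (3,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(
                "zone_fractions must be three nonnegative values summing to 1"
            )


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of a synthetic culture scene.

    Parameters
    ----------
    image_height_px, image_width_px : int
        Frame size in pixels.
    um_per_px : float
        Pixel calibration (µm per pixel); default 2.0 for a low-power
        (4x) phase-contrast objective.
    colonies : list of ColonySpec
    growth_rate_um_per_h : float
        Colony diameter growth rate before the differentiation stimulus.
    differentiation_onset_h : float or None
        Time the differentiation stimulus is added; None = maintenance only.
    edge_conversion_rate_per_h : float
        Fraction of the colony radius converted to edge morphology per
        hour after onset (outside-in: periphery before core).
    core_retention_diameter_um : float
        Colonies whose diameter at onset exceeds this keep an unconverted
        central core; smaller colonies convert fully to edge.
    textures : per-class ClassTexture
    noise_sd : float
        Additive Gaussian pixel noise.
    frame_interval_h : float
        Imaging interval; default 0.5 h (every 30 min).
    """

    image_height_px: int
    image_width_px: int
    um_per_px: float = 2.0
    colonies: tuple[ColonySpec, ...] = ()
    growth_rate_um_per_h: float = 4.0
    differentiation_onset_h: float | None = None
    edge_conversion_rate_per_h: float = 0.03
    core_retention_diameter_um: float = 400.0
    textures: dict[str, ClassTexture] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURES)
    )
    noise_sd: float = 0.01
    frame_interval_h: float = 0.5

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.growth_rate_um_per_h < 0:
            raise ValueError("growth_rate_um_per_h must be >= 0")
        if self.edge_conversion_rate_per_h < 0:
            raise ValueError("edge_conversion_rate_per_h must be >= 0")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be > 0")
        if set(self.textures) != set(CLASS_NAMES):
            raise ValueError(f"textures must cover exactly {CLASS_NAMES}")
        for name, tex in self.textures.items():
            if not (0.0 <= tex.mean <= 1.0):
                raise ValueError(f"texture mean for {name!r} outside [0, 1]")
        if isinstance(self.colonies, list):
            object.__setattr__(self, "colonies", tuple(self.colonies))


@dataclass
class GroundTruth:
    """Per-pixel label mask plus a per-colony truth table.

    ``mask`` holds labels {0 background, 1 central core, 2 core periphery,
    3 edge}; ``colonies`` has one row per colony with its diameter and the
    zone areas in µm² (pixel counts times um_per_px²).
    """

    mask: np.ndarray
    colonies: pd.DataFrame


def _zone_radii_px(
    spec: SceneSpec, colony: ColonySpec, time_h: float
) -> tuple[float, float, float]:
    """Radii (core, non-edge boundary, outer) in px at time_h.

    Growth is linear in diameter and stops at differentiation onset; after
    onset an edge front advances inward at edge_conversion_rate_per_h
    (fraction of radius per hour), converting periphery before core.
    Colonies above the retention diameter never lose the core.
    """
    onset = spec.differentiation_onset_h
    f_core, f_peri, _ = colony.zone_fractions
    if onset is None or time_h <= onset:
        grow_t = time_h
        converted = 0.0
    else:
        grow_t = onset
        converted = spec.edge_conversion_rate_per_h * (time_h - onset)
    diameter_um = colony.initial_diameter_um + spec.growth_rate_um_per_h * grow_t
    r_outer = diameter_um / 2.0 / spec.um_per_px
    boundary = (f_core + f_peri) - converted
    if onset is not None and diameter_um > spec.core_retention_diameter_um:
        boundary = max(boundary, f_core)
    boundary = max(boundary, 0.0)
    r_core = min(f_core, boundary) * r_outer
    return r_core, boundary * r_outer, r_outer


def colony_diameter_um(spec: SceneSpec, colony: ColonySpec, time_h: float) -> float:
    """Colony diameter (µm) at ``time_h`` under the scene's kinetics."""
    _, _, r_outer = _zone_radii_px(spec, colony, time_h)
    return 2.0 * r_outer * spec.um_per_px


def render_mask(spec: SceneSpec, time_h: float) -> GroundTruth:
    """Render only the ground-truth label mask (no texture) at ``time_h``.

    Much cheaper than :func:`render_frame`; used for truth-only series.
    Raises if any colony extends beyond the frame or two colonies overlap.
    """
    if time_h < 0:
        raise ValueError("time_h must be >= 0")
    h, w = spec.image_height_px, spec.image_width_px
    mask = np.zeros((h, w), dtype=np.uint8)
    rows = []
    geoms = []
    for cid, colony in enumerate(spec.colonies):
        r_core, r_mid, r_outer = _zone_radii_px(spec, colony, time_h)
        cy, cx = colony.center_rc
        if (
            cy - r_outer < 0
            or cx - r_outer < 0
            or cy + r_outer > h - 1
            or cx + r_outer > w - 1
        ):
            raise ValueError(
                f"colony {cid} extends beyond the image at t={time_h} h "
                f"(centre {colony.center_rc}, radius {r_outer:.1f} px)"
            )
        geoms.append((cid, cy, cx, r_core, r_mid, r_outer))
    for i, gi in enumerate(geoms):
        for gj in geoms[i + 1 :]:
            dist = np.hypot(gi[1] - gj[1], gi[2] - gj[2])
            if dist < gi[5] + gj[5]:
                raise ValueError(
                    f"colonies {gi[0]} and {gj[0]} overlap at t={time_h} h"
                )
    yy, xx = np.ogrid[:h, :w]
    px_area_um2 = spec.um_per_px**2
    for cid, cy, cx, r_core, r_mid, r_outer in geoms:
        r = np.hypot(yy - cy, xx - cx)
        if r_mid <= 0:
            # fully converted: the whole colony, centre pixel included, is edge
            core = np.zeros_like(r, dtype=bool)
            peri = np.zeros_like(r, dtype=bool)
            edge = r <= r_outer
        else:
            core = r <= r_core
            peri = (r > r_core) & (r <= r_mid)
            edge = (r > r_mid) & (r <= r_outer)
        mask[core] = CENTRAL_CORE
        mask[peri] = CORE_PERIPHERY
        mask[edge] = EDGE
        rows.append(
            {
                "colony_id": cid,
                "diameter_um": 2.0 * r_outer * spec.um_per_px,
                "core_um2": int(core.sum()) * px_area_um2,
                "periphery_um2": int(peri.sum()) * px_area_um2,
                "edge_um2": int(edge.sum()) * px_area_um2,
            }
        )
    colonies = pd.DataFrame(
        rows, columns=["colony_id", "diameter_um", "core_um2", "periphery_um2", "edge_um2"]
    )
    return GroundTruth(mask=mask, colonies=colonies)


def _texture_field(
    shape: tuple[int, int], tex: ClassTexture, rng: np.random.Generator
) -> np.ndarray:
    g = rng.standard_normal(shape)
    if tex.granularity_px > 0:
        g = gaussian_filter(g, tex.granularity_px)
        s = g.std()
        if s > 0:
            g /= s
    return tex.mean + tex.sd * g


def render_frame(
    spec: SceneSpec, time_h: float, seed: int
) -> tuple[np.ndarray, GroundTruth]:
    """Render one frame: a float64 grey image in [0, 1] plus ground truth.

    Each class is drawn from its own stationary smoothed-noise texture and
    composited through the label mask; additive Gaussian pixel noise of
    ``spec.noise_sd`` is applied last.  Bit-identical for identical
    (spec, time_h, seed).
    """
    truth = render_mask(spec, time_h)
    rng = np.random.default_rng(seed)
    shape = truth.mask.shape
    image = np.zeros(shape, dtype=np.float64)
    # fixed class order keeps the RNG stream independent of colony layout
    for name in CLASS_NAMES:
        fld = _texture_field(shape, spec.textures[name], rng)
        sel = truth.mask == CLASS_IDS[name]
        image[sel] = fld[sel]
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, shape)
    np.clip(image, 0.0, 1.0, out=image)
    return image, truth


def render_timeseries(
    spec: SceneSpec, n_frames: int, seed: int
) -> tuple[list[tuple[np.ndarray, GroundTruth]], pd.DataFrame]:
    """Render ``n_frames`` frames at the spec's imaging interval.

    Returns the frames (image, truth) and a long-format truth table with
    one row per colony per frame.  Per-frame RNG streams are derived from
    ``seed`` and the frame index, so a series is reproducible as a whole.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames = []
    records = []
    for i in range(n_frames):
        t = i * spec.frame_interval_h
        frame_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        image, truth = render_frame(spec, t, seed=frame_seed)
        frames.append((image, truth))
        tab = truth.colonies.copy()
        tab.insert(1, "frame", i)
        tab.insert(2, "time_h", t)
        records.append(tab)
    truth_table = pd.concat(records, ignore_index=True) if records else pd.DataFrame()
    return frames, truth_table


def mask_timeseries(spec: SceneSpec, n_frames: int) -> tuple[list[GroundTruth], pd.DataFrame]:
    """Truth-only analogue of :func:`render_timeseries` (no textures)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    truths = []
    records = []
    for i in range(n_frames):
        t = i * spec.frame_interval_h
        truth = render_mask(spec, t)
        truths.append(truth)
        tab = truth.colonies.copy()
        tab.insert(1, "frame", i)
        tab.insert(2, "time_h", t)
        records.append(tab)
    truth_table = pd.concat(records, ignore_index=True) if records else pd.DataFrame()
    return truths, truth_table


def mask_coverage(mask: np.ndarray) -> dict[str, float]:
    """Per-class pixel coverage (%) of a label mask — the truth analogue of
    classifier coverage."""
    total = mask.size
    return {
        name: 100.0 * float(np.count_nonzero(mask == CLASS_IDS[name])) / total
        for name in CLASS_NAMES
    }


@dataclass(frozen=True)
class CountTableSpec:
    """Generator for synthetic (coverage, cell count) tables.

    Counts follow ``beta0 + beta_core*core% + beta_periphery*periphery% +
    beta_edge*edge% + N(0, noise_sd_cells)``.  Defaults put far more
    weight on the dense central core than on the sparse edge, reflecting
    the cell-density ordering of the zones; coverages are sampled
    uniformly over per-class ranges.
    """

    n_samples: int = 40
    beta0: float = 2.0e5
    beta_core: float = 3.0e4
    beta_periphery: float = 1.8e4
    beta_edge: float = 4.0e3
    noise_sd_cells: float = 5.0e4
    core_range: tuple[float, float] = (0.0, 40.0)
    periphery_range: tuple[float, float] = (0.0, 30.0)
    edge_range: tuple[float, float] = (0.0, 30.0)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd_cells < 0:
            raise ValueError("noise_sd_cells must be >= 0")
        for lo, hi in (self.core_range, self.periphery_range, self.edge_range):
            if not (0 <= lo <= hi):
                raise ValueError("coverage ranges must satisfy 0 <= lo <= hi")


def generate_count_table(spec: CountTableSpec, seed: int) -> pd.DataFrame:
    """Draw a (edge_pct, periphery_pct, core_pct, cell_count) table.

    Negative generated counts are clipped at 0 with a logged warning.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    core = rng.uniform(*spec.core_range, n)
    peri = rng.uniform(*spec.periphery_range, n)
    edge = rng.uniform(*spec.edge_range, n)
    counts = (
        spec.beta0
        + spec.beta_core * core
        + spec.beta_periphery * peri
        + spec.beta_edge * edge
    )
    if spec.noise_sd_cells > 0:
        counts = counts + rng.normal(0.0, spec.noise_sd_cells, n)
    n_neg = int(np.count_nonzero(counts < 0))
    if n_neg:
        logger.warning("clipped %d negative generated cell counts at 0", n_neg)
        counts = np.clip(counts, 0.0, None)
    return pd.DataFrame(
        {
            "edge_pct": edge,
            "periphery_pct": peri,
            "core_pct": core,
            "cell_count": counts,
        }
    )
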