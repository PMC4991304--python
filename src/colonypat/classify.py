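"""Whole-image tile classification against a taught patch library.

Images are tiled into non-overlapping 64x64 squares (partial border
tiles are excluded and reported through the analysed-area fraction);
each tile's texture descriptor is matched against the library by
k-nearest-neighbour search on z-scored features, and per-class coverage
percentages are computed over the analysed tiles.  This is the
quantitative readout the rest of the package consumes: coverage time
series for monitoring, label maps for colony segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .library import PATCH_SIZE, PatchLibrary, compute_features
from .synthetic import CLASS_NAMES

# deterministic tie-break order for equal votes and equal mean distance
CLASS_ORDER = {name: i for i, name in enumerate(CLASS_NAMES)}


@dataclass(frozen=True)
class TileGrid:
    """Non-overlapping full tiles of an image; windows are half-open, 0-based."""

    image_height_px: int
    image_width_px: int
    tile_size: int
    n_rows: int
    n_cols: int

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def analyzed_fraction(self) -> float:
        covered = (self.n_rows * self.tile_size) * (self.n_cols * self.tile_size)
        return covered / (self.image_height_px * self.image_width_px)

    def windows(self):
        """Yield (row, col, (r0, r1, c0, c1)) for every full tile."""
        s = self.tile_size
        for i in range(self.n_rows):
            for j in range(self.n_cols):
                yield i, j, (i * s, (i + 1) * s, j * s, (j + 1) * s)


def tile_grid(height_px: int, width_px: int, tile_size: int = PATCH_SIZE) -> TileGrid:
    """Lay out floor(h/s) x floor(w/s) full tiles; border residue excluded."""
    if height_px < tile_size or width_px < tile_size:
        raise ValueError(
            f"image {height_px}x{width_px} smaller than one {tile_size}px tile"
        )
    return TileGrid(
        image_height_px=height_px,
        image_width_px=width_px,
        tile_size=tile_size,
        n_rows=height_px // tile_size,
        n_cols=width_px // tile_size,
    )


@dataclass
class TileLabelMap:
    """Per-tile class labels with match scores (mean k-NN distance)."""

    grid: TileGrid
    labels: np.ndarray  # (n_rows, n_cols) of class-name strings
    scores: np.ndarray  # (n_rows, n_cols) of mean neighbour distances
    library_version: str = "1"
    source_id: str = ""
    frame_index: int | None = None

    def label_codes(self) -> np.ndarray:
        """Labels as integer codes 0..3 (background..edge)."""
        codes = np.zeros(self.labels.shape, dtype=np.uint8)
        for name, code in CLASS_ORDER.items():
            codes[self.labels == name] = code
        return codes


@dataclass
class CoverageRecord:
    """Per-class tile counts and percentages of the analysed area."""

    counts: dict[str, int]
    percentages: dict[str, float]
    n_tiles: int
    analyzed_fraction: float
    condition: str = ""
    time_h: float | None = None

    @classmethod
    def from_labels(
        cls,
        labels: np.ndarray,
        analyzed_fraction: float = 1.0,
        condition: str = "",
        time_h: float | None = None,
    ) -> "CoverageRecord":
        n = labels.size
        counts = {name: int(np.sum(labels == name)) for name in CLASS_NAMES}
        percentages = {name: 100.0 * counts[name] / n for name in CLASS_NAMES}
        return cls(
            counts=counts,
            percentages=percentages,
            n_tiles=n,
            analyzed_fraction=analyzed_fraction,
            condition=condition,
            time_h=time_h,
        )

    def cell_coverage_pct(self) -> float:
        """Total non-background coverage (%) — the confluence analogue."""
        return 100.0 - self.percentages["background"]

    def edge_pct(self, of_cells: bool = False) -> float:
        """Edge coverage as % of analysed area, or of cell area if
        ``of_cells`` (denominator = non-background tiles)."""
        if not of_cells:
            return self.percentages["edge"]
        n_cells = self.n_tiles - self.counts["background"]
        if n_cells == 0:
            return 0.0
        return 100.0 * self.counts["edge"] / n_cells


def _vote(labels: np.ndarray, dists: np.ndarray) -> tuple[str, float]:
    """Majority vote with deterministic tie-breaking.

    Ties on votes are broken by smaller mean distance among the tied
    classes, then by fixed class order background < central_core <
    core_periphery < edge.
    """
    votes = {name: 0 for name in CLASS_NAMES}
    sums = {name: 0.0 for name in CLASS_NAMES}
    for lab, d in zip(labels, dists):
        votes[lab] += 1
        sums[lab] += d
    best = max(votes.values())
    tied = [name for name in CLASS_NAMES if votes[name] == best]
    # sort by (mean distance within class, class order); CLASS_NAMES
    # iteration already yields class order, and sort is stable
    winner = min(tied, key=lambda name: sums[name] / votes[name])
    return winner, float(dists.mean())


def classify_tile(
    tile: np.ndarray, library: PatchLibrary, k: int = 5
) -> tuple[str, float]:
    """Classify one 64x64 tile by k-NN over the library's z-scored features.

    Returns the majority class among the k nearest library patches
    (Euclidean distance) and the mean distance of those k as the match
    score (lower = better match).
    """
    if k < 1 or k > len(library):
        raise ValueError(f"k={k} outside [1, {len(library)}]")
    vec = library.zscore(compute_features(tile, library.feature_config))
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite features for tile")
    dists = np.sqrt(((library.zscored_features - vec) ** 2).sum(axis=1))
    order = np.argpartition(dists, k - 1)[:k]
    return _vote(library.labels[order], dists[order])


def classify_image(
    image: np.ndarray,
    library: PatchLibrary,
    k: int = 5,
    source_id: str = "",
    condition: str = "",
    time_h: float | None = None,
    frame_index: int | None = None,
) -> tuple[TileLabelMap, CoverageRecord]:
    """Tile an image and classify every full tile against the library."""
    image = np.asarray(image, dtype=np.float64)
    grid = tile_grid(*image.shape)
    feats = np.empty((grid.n_tiles, library.feature_config.n_features))
    coords = []
    for idx, (i, j, (r0, r1, c0, c1)) in enumerate(grid.windows()):
        try:
            feats[idx] = compute_features(image[r0:r1, c0:c1], library.feature_config)
        except ValueError as exc:
            raise ValueError(f"tile ({i}, {j}): {exc}") from exc
        coords.append((i, j))
    z = (feats - library.center) / library.scale
    if not np.all(np.isfinite(z)):
        bad = coords[int(np.argwhere(~np.all(np.isfinite(z), axis=1))[0, 0])]
        raise ValueError(f"non-finite features for tile {bad}")
    if k < 1 or k > len(library):
        raise ValueError(f"k={k} outside [1, {len(library)}]")
    dmat = cdist(z, library.zscored_features)
    labels = np.empty((grid.n_rows, grid.n_cols), dtype=object)
    scores = np.zeros((grid.n_rows, grid.n_cols))
    for idx, (i, j) in enumerate(coords):
        order = np.argpartition(dmat[idx], k - 1)[:k]
        labels[i, j], scores[i, j] = _vote(library.labels[order], dmat[idx, order])
    labelmap = TileLabelMap(
        grid=grid,
        labels=labels,
        scores=scores,
        library_version=library.version,
        source_id=source_id,
        frame_index=frame_index,
    )
    record = CoverageRecord.from_labels(
        labels, grid.analyzed_fraction, condition=condition, time_h=time_h
    )
    return labelmap, record


def coverage_timeseries(
    images_with_times: list[tuple[np.ndarray, float]],
    library: PatchLibrary,
    k: int = 5,
    condition: str = "",
) -> list[CoverageRecord]:
    """Classify a time-ordered image series into one CoverageRecord per frame."""
    times = [t for _, t in images_with_times]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing (no duplicates)")
    records = []
    for i, (image, t) in enumerate(images_with_times):
        _, rec = classify_image(
            image, library, k=k, condition=condition, time_h=t, frame_index=i
        )
        records.append(rec)
    return records


# colour code matching the conventional overlay: core red, periphery blue,
# edge green, background black
OVERLAY_COLORS = {
    "background": (0.0, 0.0, 0.0),
    "central_core": (1.0, 0.0, 0.0),
    "core_periphery": (0.0, 0.0, 1.0),
    "edge": (0.0, 1.0, 0.0),
}


def overlay_rgb(labelmap: TileLabelMap) -> np.ndarray:
    """Colour-coded RGB rendering of a label map at tile resolution."""
    rgb = np.zeros((*labelmap.labels.shape, 3))
    for name, color in OVERLAY_COLORS.items():
        rgb[labelmap.labels == name] = color
    return rgb
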