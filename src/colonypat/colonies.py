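"""Per-colony analysis on tile label maps.

Individual colonies are segmented as 4-connected components of
non-background tiles, measured (area, equivalent circular diameter,
per-class composition), linked through time by greedy nearest-centroid
matching, and related to process outcomes: the inverse correlation
between initial colony size and the fraction converting to edge
morphology under a differentiation stimulus, diameter-threshold process
triggers, and the post-stimulus rate of edge-coverage change.

Sizes are tile-resolution: area = tiles x (tile_size x um_per_px)^2 and
diameter is the equivalent circular diameter 2*sqrt(area/pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sstats

from .classify import TileLabelMap
from .synthetic import CLASS_NAMES

MIN_COLONY_TILES = 2  # smaller components discarded as debris
MAX_LINK_DISPLACEMENT_TILES = 2.0


@dataclass
class ColonyRecord:
    """One segmented colony in one frame."""

    colony_id: int
    frame_index: int | None
    time_h: float | None
    tile_count: int
    area_um2: float
    diameter_um: float
    composition_pct: dict[str, float]  # of colony tiles; background is 0
    centroid_tiles: tuple[float, float]

    @property
    def edge_fraction_pct(self) -> float:
        return self.composition_pct["edge"]


def segment_colonies(
    labelmap: TileLabelMap,
    um_per_px: float,
    min_tiles: int = MIN_COLONY_TILES,
    time_h: float | None = None,
) -> list[ColonyRecord]:
    """Segment colonies as 4-connected components of non-background tiles."""
    codes = labelmap.label_codes()
    cell = codes != 0
    comp, n_comp = ndimage.label(cell, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    tile_um = labelmap.grid.tile_size * um_per_px
    records = []
    cid = 0
    for comp_id in range(1, n_comp + 1):
        sel = comp == comp_id
        n_tiles = int(sel.sum())
        if n_tiles < min_tiles:
            continue
        area = n_tiles * tile_um**2
        composition = {
            name: 100.0 * float(np.sum(sel & (labelmap.labels == name))) / n_tiles
            for name in CLASS_NAMES
        }
        rr, cc = np.nonzero(sel)
        records.append(
            ColonyRecord(
                colony_id=cid,
                frame_index=labelmap.frame_index,
                time_h=time_h,
                tile_count=n_tiles,
                area_um2=area,
                diameter_um=2.0 * np.sqrt(area / np.pi),
                composition_pct=composition,
                centroid_tiles=(float(rr.mean()), float(cc.mean())),
            )
        )
        cid += 1
    return records


@dataclass
class ColonyTrack:
    """One colony followed over frames."""

    track_id: int
    records: list[ColonyRecord]

    @property
    def times_h(self) -> list[float | None]:
        return [r.time_h for r in self.records]

    def record_at_or_before(self, time_h: float) -> ColonyRecord | None:
        best = None
        for r in self.records:
            if r.time_h is not None and r.time_h <= time_h:
                best = r
        return best

    def record_at_or_after(self, time_h: float) -> ColonyRecord | None:
        for r in self.records:
            if r.time_h is not None and r.time_h >= time_h:
                return r
        return None


def track_colonies(
    frames: list[list[ColonyRecord]],
    max_displacement_tiles: float = MAX_LINK_DISPLACEMENT_TILES,
) -> list[ColonyTrack]:
    """Greedy nearest-centroid frame-to-frame linking.

    Candidate links within ``max_displacement_tiles`` are taken smallest
    distance first (ties by lower previous-track id, then lower colony
    id, so the result is independent of input ordering); unmatched
    colonies start new tracks and a track that finds no match ends.
    """
    tracks: list[ColonyTrack] = []
    active: list[ColonyTrack] = []
    for frame in frames:
        frame = sorted(frame, key=lambda r: r.colony_id)
        pairs = []
        for ti, track in enumerate(active):
            last = track.records[-1]
            for rec in frame:
                d = float(np.hypot(
                    last.centroid_tiles[0] - rec.centroid_tiles[0],
                    last.centroid_tiles[1] - rec.centroid_tiles[1],
                ))
                if d <= max_displacement_tiles:
                    pairs.append((d, ti, rec.colony_id, rec))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_tracks: set[int] = set()
        used_records: set[int] = set()
        next_active = []
        for d, ti, rid, rec in pairs:
            if ti in used_tracks or rid in used_records:
                continue
            active[ti].records.append(rec)
            used_tracks.add(ti)
            used_records.add(rid)
            next_active.append(active[ti])
        for rec in frame:
            if rec.colony_id not in used_records:
                track = ColonyTrack(track_id=len(tracks), records=[rec])
                tracks.append(track)
                next_active.append(track)
        next_active.sort(key=lambda t: t.track_id)
        active = next_active
    return tracks


@dataclass
class SizeResponseResult:
    """Initial colony diameter vs final edge fraction across a population."""

    table: pd.DataFrame  # columns: track_id, initial_diameter_um, final_edge_pct
    pearson_r: float | None
    slope_pct_per_um: float | None
    intercept_pct: float | None


def size_response(
    tracks: list[ColonyTrack], stimulus_time_h: float, response_horizon_h: float
) -> SizeResponseResult:
    """Relate colony size at the stimulus to edge conversion at the horizon.

    For each track spanning both times, takes the equivalent diameter at
    the stimulus and the per-colony edge fraction at the horizon, and
    fits edge% ~ diameter by OLS with the Pearson correlation.  With no
    size variance the correlation is undefined and reported as None.
    """
    rows = []
    for track in tracks:
        start = track.record_at_or_before(stimulus_time_h)
        end = track.record_at_or_after(response_horizon_h)
        if start is None or end is None:
            continue
        rows.append(
            {
                "track_id": track.track_id,
                "initial_diameter_um": start.diameter_um,
                "final_edge_pct": end.edge_fraction_pct,
            }
        )
    if len(rows) < 3:
        raise ValueError(
            f"need >= 3 tracks spanning the stimulus and horizon, got {len(rows)}"
        )
    table = pd.DataFrame(rows)
    x = table["initial_diameter_um"].to_numpy()
    y = table["final_edge_pct"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in sizes or responses; correlation undefined")
        return SizeResponseResult(table, None, None, None)
    r = float(sstats.pearsonr(x, y).statistic)
    slope, intercept = np.polyfit(x, y, 1)
    return SizeResponseResult(table, r, float(slope), float(intercept))


@dataclass
class TriggerResult:
    """Outcome of a mean-diameter process trigger."""

    threshold_um: float
    trigger_time_h: float | None
    mean_diameter_series: pd.DataFrame  # columns: time_h, mean_diameter_um


def trigger_on_mean_diameter(
    frames: list[list[ColonyRecord]], threshold_um: float
) -> TriggerResult:
    """Earliest frame whose mean colony diameter reaches ``threshold_um``.

    Emulates adding a process action (e.g. a differentiation stimulus)
    when the culture's mean colony diameter crosses a specification.
    """
    if not frames or any(len(f) == 0 for f in frames):
        raise ValueError("every frame must contain at least one colony")
    rows = [
        {
            "time_h": frame[0].time_h,
            "mean_diameter_um": float(np.mean([r.diameter_um for r in frame])),
        }
        for frame in frames
    ]
    series = pd.DataFrame(rows)
    hit = series[series["mean_diameter_um"] >= threshold_um]
    t = float(hit["time_h"].iloc[0]) if len(hit) else None
    return TriggerResult(threshold_um=threshold_um, trigger_time_h=t, mean_diameter_series=series)


def response_rate(
    times_h, edge_pct, window_start_h: float, window_h: float
) -> float:
    """OLS slope (% per hour) of edge coverage over a post-trigger window."""
    times_h = np.asarray(times_h, dtype=float)
    edge_pct = np.asarray(edge_pct, dtype=float)
    sel = (times_h >= window_start_h) & (times_h <= window_start_h + window_h)
    if sel.sum() < 3:
        raise ValueError("need >= 3 points in the response window")
    slope, _ = np.polyfit(times_h[sel], edge_pct[sel], 1)
    return float(slope)
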