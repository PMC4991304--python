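"""Sampling-precision and monitoring statistics for coverage measurements.

Because imaging is noninvasive, precision is set by how many random
fields of view are sampled per culture: the SEM of per-image coverage
drops as 1/sqrt(n), so a required confidence-interval half-width maps
directly to a required image sample size.  This module provides those
design calculations (normal-theory, z = 1.96), empirical SEM-vs-n curves
by subsampling a finite image pool, and detection of the earliest
sustained statistical separation between two monitored conditions
(Welch t-test per timepoint, sustained over several consecutive frames
to ignore transient imaging artifacts such as post-feed refocusing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

Z95 = 1.96


def sem(values) -> float:
    """Standard error of the mean: sample sd (ddof=1) / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("sem requires at least 2 values")
    return float(values.std(ddof=1) / np.sqrt(n))


def ci95(values) -> tuple[float, float]:
    """Mean and 95% CI half-width (1.96 x SEM) of per-image coverages."""
    values = np.asarray(values, dtype=float)
    return float(values.mean()), Z95 * sem(values)


def sample_size_for_halfwidth(sigma: float, halfwidth: float) -> int:
    """Images needed so the expected 95% CI half-width is <= ``halfwidth``.

    ``sigma`` is the per-image coverage sd.  n = ceil((1.96*sigma/hw)^2),
    floored at 2 (an SEM needs at least two images).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    # tiny epsilon guards float round-up at exact integer solutions
    return max(2, int(np.ceil((Z95 * sigma / halfwidth) ** 2 - 1e-9)))


def sem_vs_n_curve(
    values, n_grid, n_resamples: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Empirical SEM against sample size by subsampling an image pool.

    For each n in ``n_grid``, draws ``n_resamples`` subsamples without
    replacement from ``values`` and averages the subsample mean, SEM and
    CI half-width.  Deterministic given ``seed``.  Returns a table with
    columns (n, mean_pct, sem_pct, ci95_halfwidth_pct).
    """
    values = np.asarray(values, dtype=float)
    n_grid = [int(n) for n in n_grid]
    if any(n < 2 for n in n_grid):
        raise ValueError("every n in n_grid must be >= 2")
    if max(n_grid) > values.size:
        raise ValueError("n_grid exceeds the number of available values")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        if n == values.size:
            means, sems = [values.mean()], [sem(values)]
        else:
            means, sems = [], []
            for _ in range(n_resamples):
                sub = values[rng.choice(values.size, size=n, replace=False)]
                means.append(sub.mean())
                sems.append(sem(sub))
        rows.append(
            {
                "n": n,
                "mean_pct": float(np.mean(means)),
                "sem_pct": float(np.mean(sems)),
                "ci95_halfwidth_pct": Z95 * float(np.mean(sems)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SeparationResult:
    """Per-timepoint Welch p-values and the earliest sustained separation."""

    times_h: np.ndarray
    p_values: np.ndarray
    separation_time_h: float | None
    alpha: float
    sustain: int


def separation_time(
    series_a: np.ndarray,
    series_b: np.ndarray,
    times_h,
    alpha: float = 0.05,
    sustain: int = 3,
) -> SeparationResult:
    """Earliest sustained statistical separation of two monitored conditions.

    ``series_a``/``series_b`` are (n_timepoints, n_images) arrays of
    per-image coverage at shared timepoints.  A Welch two-sample t-test
    is run per timepoint; the separation time is the earliest timepoint
    where p <= alpha holds for ``sustain`` consecutive frames (None if
    never).  Symmetric in the two series.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    times_h = np.asarray(times_h, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("series must be 2-D (n_timepoints, n_images)")
    if a.shape[0] != b.shape[0] or a.shape[0] != times_h.size:
        raise ValueError("series and time grid lengths do not match")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 images per condition per timepoint")
    if sustain < 1:
        raise ValueError("sustain must be >= 1")
    p = np.empty(times_h.size)
    for i in range(times_h.size):
        if np.allclose(a[i], a[i][0]) and np.allclose(b[i], b[i][0]):
            # both samples constant: identical -> no evidence, else certain
            p[i] = 1.0 if a[i][0] == b[i][0] else 0.0
        else:
            p[i] = sstats.ttest_ind(a[i], b[i], equal_var=False).pvalue
    sep: float | None = None
    below = p <= alpha
    for i in range(times_h.size - sustain + 1):
        if below[i : i + sustain].all():
            sep = float(times_h[i])
            break
    return SeparationResult(
        times_h=times_h, p_values=p, separation_time_h=sep, alpha=alpha, sustain=sustain
    )
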