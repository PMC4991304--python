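"""Taught reference libraries of 64x64 image patches.

The classifier in this package is "taught" the four colony morphologies
(background, central core, core periphery, edge cells) from curated
example patches, mirroring how live-cell imaging platforms build
reference libraries for area classification.  A library stores, per
class, a set of 64x64 grey patches together with a fixed-length texture
descriptor per patch and pooled z-scoring parameters, and round-trips
losslessly through a directory of PNG files plus a JSON manifest.

The descriptor concatenates first-order intensity statistics, a 16-bin
intensity histogram, gradient-magnitude statistics, and a
rotation-invariant uniform local-binary-pattern histogram (radius 1,
8 neighbours) — intensity plus granularity, which is what distinguishes
the dense dark core from the sparse bright edge.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import stats as sstats
from skimage.feature import local_binary_pattern

from .synthetic import CLASS_NAMES

logger = logging.getLogger(__name__)

PATCH_SIZE = 64
_PNG_MAX = 65535  # patches are stored as 16-bit PNG

SCALE_FLOOR = 1e-8


@dataclass(frozen=True)
class FeatureConfig:
    """Descriptor settings; the feature length is fixed by these."""

    n_hist_bins: int = 16
    lbp_radius: int = 1
    lbp_points: int = 8

    @property
    def n_lbp_bins(self) -> int:
        # 'uniform' rotation-invariant LBP has P+2 codes
        return self.lbp_points + 2

    @property
    def n_features(self) -> int:
        # mean, sd, skewness + histogram + gradient mean/sd + LBP histogram
        return 3 + self.n_hist_bins + 2 + self.n_lbp_bins


@dataclass(frozen=True)
class Patch:
    """A 64x64 grey patch in [0, 1] with its class and provenance.

    Pixels are quantised to the 16-bit grid on construction so that disk
    round trips through PNG are exact.
    """

    pixels: np.ndarray
    class_label: str
    source_id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("patch contains non-finite values")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("patch values must lie in [0, 1]")
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_label!r}")
        px = np.round(px * _PNG_MAX) / _PNG_MAX
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)


def compute_features(patch: Patch | np.ndarray, config: FeatureConfig | None = None) -> np.ndarray:
    """Fixed-length texture descriptor of one patch.

    Blocks, in order: (mean, sd, skewness); normalised intensity
    histogram over [0, 1]; gradient-magnitude mean and sd; normalised
    rotation-invariant uniform LBP histogram.  Defined for constant
    patches (sd-dependent entries are 0).
    """
    config = config or FeatureConfig()
    px = patch.pixels if isinstance(patch, Patch) else np.asarray(patch, dtype=np.float64)
    if px.shape != (PATCH_SIZE, PATCH_SIZE):
        raise ValueError(f"expected a {PATCH_SIZE}x{PATCH_SIZE} patch, got {px.shape}")
    if not np.all(np.isfinite(px)):
        raise ValueError("patch contains non-finite values")
    mean = px.mean()
    sd = px.std(ddof=0)
    skew = float(sstats.skew(px, axis=None)) if sd > 0 else 0.0
    hist, _ = np.histogram(px, bins=config.n_hist_bins, range=(0.0, 1.0))
    hist = hist / px.size
    gy, gx = np.gradient(px)
    gmag = np.hypot(gy, gx)
    # LBP on the 16-bit grid: integer comparisons are stable where float
    # ties would be noise-driven
    lbp_img = np.round(px * _PNG_MAX).astype(np.uint16)
    lbp = local_binary_pattern(lbp_img, config.lbp_points, config.lbp_radius, method="uniform")
    # drop the 1-px border, where the circular neighbourhood is truncated
    core = lbp[1:-1, 1:-1]
    lbp_hist, _ = np.histogram(core, bins=config.n_lbp_bins, range=(0, config.n_lbp_bins))
    lbp_hist = lbp_hist / core.size
    vec = np.concatenate(
        [[mean, sd, skew], hist, [gmag.mean(), gmag.std(ddof=0)], lbp_hist]
    )
    assert vec.size == config.n_features
    return vec


def extract_patches(
    image: np.ndarray,
    mask: np.ndarray,
    class_label: str,
    n: int,
    purity_threshold: float = 0.9,
    seed: int = 0,
) -> list[Patch]:
    """Sample up to ``n`` pure-class 64x64 patches from an annotated image.

    A window is eligible when at least ``purity_threshold`` of its mask
    pixels carry ``class_label``'s code.  Windows are sampled uniformly
    without replacement over all eligible top-left positions (windows may
    overlap).  Returns fewer than ``n`` with a logged warning when the
    image does not contain enough eligible windows.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask must have the same shape")
    if not (0 < purity_threshold <= 1):
        raise ValueError("purity_threshold must be in (0, 1]")
    if class_label not in CLASS_NAMES:
        raise ValueError(f"unknown class {class_label!r}")
    h, w = image.shape
    if h < PATCH_SIZE or w < PATCH_SIZE:
        return []
    code = CLASS_NAMES.index(class_label)
    ind = (mask == code).astype(np.float64)
    # summed-area table -> per-window class-pixel counts for every position
    sat = np.pad(ind.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    s = PATCH_SIZE
    counts = sat[s:, s:] - sat[:-s, s:] - sat[s:, :-s] + sat[:-s, :-s]
    purity = counts / (s * s)
    eligible = np.argwhere(purity >= purity_threshold - 1e-12)
    rng = np.random.default_rng(seed)
    if len(eligible) < n:
        logger.warning(
            "only %d eligible windows for class %s (requested %d)",
            len(eligible), class_label, n,
        )
        chosen = eligible
    else:
        idx = rng.choice(len(eligible), size=n, replace=False)
        chosen = eligible[np.sort(idx)]
    patches = []
    for r, c in chosen:
        patches.append(
            Patch(
                pixels=image[r : r + s, c : c + s],
                class_label=class_label,
                source_id=f"r{r}c{c}",
            )
        )
    return patches


@dataclass
class PatchLibrary:
    """The four taught reference libraries with pooled feature scaling.

    ``features`` rows are raw descriptors in patch order; ``labels``
    holds the matching class names.  ``center``/``scale`` are the pooled
    per-dimension z-scoring parameters (scale floored at 1e-8 so
    constant dimensions stay finite).
    """

    patches: list[Patch]
    features: np.ndarray
    labels: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    version: str = "1"

    def __len__(self) -> int:
        return len(self.patches)

    def class_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.labels == name)) for name in CLASS_NAMES}

    @property
    def zscored_features(self) -> np.ndarray:
        return (self.features - self.center) / self.scale

    def zscore(self, vec: np.ndarray) -> np.ndarray:
        return (np.asarray(vec) - self.center) / self.scale


def build_library(
    patches_by_class: dict[str, list[Patch]],
    feature_config: FeatureConfig | None = None,
) -> PatchLibrary:
    """Assemble a PatchLibrary from per-class patch lists.

    All four morphological classes must be present and nonempty.
    Features are z-scored with centre/scale pooled over every class so
    that inter-class distances are comparable.
    """
    feature_config = feature_config or FeatureConfig()
    for name in CLASS_NAMES:
        if not patches_by_class.get(name):
            raise ValueError(f"missing or empty class {name!r}")
    patches: list[Patch] = []
    labels: list[str] = []
    for name in CLASS_NAMES:
        for p in patches_by_class[name]:
            if p.class_label != name:
                raise ValueError(
                    f"patch labelled {p.class_label!r} listed under class {name!r}"
                )
            patches.append(p)
            labels.append(name)
    features = np.array([compute_features(p, feature_config) for p in patches])
    center = features.mean(axis=0)
    scale = np.maximum(features.std(axis=0, ddof=0), SCALE_FLOOR)
    return PatchLibrary(
        patches=patches,
        features=features,
        labels=np.array(labels),
        center=center,
        scale=scale,
        feature_config=feature_config,
    )


def save_library(library: PatchLibrary, path: str | Path) -> None:
    """Write a library as per-class directories of 16-bit PNGs + manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    counters: dict[str, int] = {}
    for patch in library.patches:
        cls = patch.class_label
        i = counters.get(cls, 0)
        counters[cls] = i + 1
        (path / cls).mkdir(exist_ok=True)
        fname = f"{cls}/{i:04d}.png"
        arr = np.round(patch.pixels * _PNG_MAX).astype(np.uint16)
        iio.imwrite(path / fname, arr)
        entries.append({"class": cls, "source_id": patch.source_id, "filename": fname})
    manifest = {
        "version": library.version,
        "feature_config": {
            "n_hist_bins": library.feature_config.n_hist_bins,
            "lbp_radius": library.feature_config.lbp_radius,
            "lbp_points": library.feature_config.lbp_points,
        },
        "center": library.center.tolist(),
        "scale": library.scale.tolist(),
        "patches": entries,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_library(
    path: str | Path, feature_config: FeatureConfig | None = None
) -> PatchLibrary:
    """Load a saved library, recomputing features and verifying the manifest.

    Raises if patch files listed in the manifest are missing, malformed,
    or if ``feature_config`` disagrees with the stored configuration.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    stored_config = FeatureConfig(**manifest["feature_config"])
    if feature_config is not None and feature_config != stored_config:
        raise ValueError(
            f"feature_config mismatch: requested {feature_config}, "
            f"manifest has {stored_config}"
        )
    problems = []
    by_class: dict[str, list[Patch]] = {name: [] for name in CLASS_NAMES}
    for entry in manifest["patches"]:
        fpath = path / entry["filename"]
        if not fpath.exists():
            problems.append(f"missing patch file {entry['filename']}")
            continue
        arr = iio.imread(fpath)
        if arr.shape != (PATCH_SIZE, PATCH_SIZE):
            problems.append(f"bad patch shape in {entry['filename']}: {arr.shape}")
            continue
        pixels = arr.astype(np.float64) / _PNG_MAX
        by_class.setdefault(entry["class"], []).append(
            Patch(pixels=pixels, class_label=entry["class"], source_id=entry["source_id"])
        )
    if problems:
        raise ValueError("library manifest mismatch: " + "; ".join(problems))
    library = build_library(by_class, stored_config)
    # pooled normalisation comes from the manifest, not recomputation, so a
    # loaded library classifies identically to the one that was saved
    library.center = np.asarray(manifest["center"], dtype=np.float64)
    library.scale = np.asarray(manifest["scale"], dtype=np.float64)
    library.version = str(manifest["version"])
    return library
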