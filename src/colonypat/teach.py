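"""Library-teaching workflow on synthetic scenes.

Builds taught reference libraries the way an operator would on real
cultures: render scenes containing a large colony with generous pure
regions of every morphology, then harvest high-purity 64x64 patches per
class.  Teaching scenes use wider periphery/edge bands than the default
colony geometry so that pure 64-px windows exist inside each annulus.
"""

from __future__ import annotations

import numpy as np

from .library import FeatureConfig, Patch, PatchLibrary, build_library, extract_patches
from .synthetic import CLASS_NAMES, ColonySpec, SceneSpec, render_frame

# zone-width fractions widened so every band admits pure 64-px windows
TEACHING_ZONE_FRACTIONS = (0.40, 0.30, 0.30)
TEACHING_IMAGE_PX = 1024
TEACHING_COLONY_DIAMETER_UM = 1600.0


def teaching_scene(um_per_px: float = 2.0) -> SceneSpec:
    """A single large colony filling most of the frame, with wide zones."""
    c = TEACHING_IMAGE_PX / 2
    return SceneSpec(
        image_height_px=TEACHING_IMAGE_PX,
        image_width_px=TEACHING_IMAGE_PX,
        um_per_px=um_per_px,
        colonies=(
            ColonySpec(
                center_rc=(c, c),
                initial_diameter_um=TEACHING_COLONY_DIAMETER_UM,
                zone_fractions=TEACHING_ZONE_FRACTIONS,
            ),
        ),
        growth_rate_um_per_h=0.0,
    )


def sample_class_patches(
    n_per_class: int,
    seed: int,
    purity_threshold: float = 0.9,
    n_scenes: int = 2,
    um_per_px: float = 2.0,
) -> dict[str, list[Patch]]:
    """Harvest ``n_per_class`` pure patches of every class from seeded scenes.

    Patches are split across ``n_scenes`` independently textured scenes
    for diversity; disjoint seeds give disjoint patch sets, so held-out
    evaluation patches can be drawn with a different ``seed``.
    """
    spec = teaching_scene(um_per_px)
    per_scene = int(np.ceil(n_per_class / n_scenes))
    out: dict[str, list[Patch]] = {name: [] for name in CLASS_NAMES}
    for s in range(n_scenes):
        scene_seed = int(np.random.SeedSequence([seed, s]).generate_state(1)[0] % (2**31))
        image, truth = render_frame(spec, time_h=0.0, seed=scene_seed)
        for name in CLASS_NAMES:
            need = min(per_scene, n_per_class - len(out[name]))
            if need <= 0:
                continue
            got = extract_patches(
                image, truth.mask, name, need,
                purity_threshold=purity_threshold, seed=scene_seed + 1,
            )
            for p in got:
                out[name].append(
                    Patch(p.pixels, p.class_label, f"scene{s}:{p.source_id}")
                )
    return out


def build_default_library(
    n_per_class: int = 200,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
) -> PatchLibrary:
    """Teach a library of ``n_per_class`` patches per morphology (default 200,
    the practical precision/teaching-time trade-off)."""
    patches = sample_class_patches(n_per_class, seed=seed)
    return build_library(patches, feature_config)
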