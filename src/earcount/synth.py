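"""Seeded synthetic field scenes with exact polygon ground truth.

Each scene is an RGB image of textured, golden-hued, ellipse-shaped
"ears" over a vegetation-like background, with one 16-vertex polygon per
ear.  Scenes come in four density levels with ascending count ranges, and
the cluttered background adds elongated leaf-like strokes drawn from the
same hue range as the ears — emulating the field situation where leaves
can be mistaken for ears.  Everything (placement, shape, texture,
clutter) derives from one seed, so scenes are bitwise reproducible.

These scenes are fixtures for testing the counting pipeline end to end;
they model instance density, overlap, occlusion-free polygon truth and
color-similar clutter, not the photometric variation of real field
imagery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotations import ImageRecord, PolygonAnnotation, to_coco
from .density import TargetCenters

# count ranges per level; ear size scales with resolution, so the same
# counts apply at any image size (a 128^2 test scene holds the same number
# of proportionally smaller ears as a 1024^2 field tile)
LEVEL_COUNTS = {1: (5, 15), 2: (15, 40), 3: (40, 80), 4: (80, 150)}
_REFERENCE_SIZE = 1024


@dataclass(frozen=True)
class SceneConfig:
    image_size: tuple[int, int] = (1024, 1024)
    level: int = 1
    count_range: tuple[int, int] | None = None  # default: level table, scaled
    ear_major: tuple[float, float] | None = None  # px range; default scales
    ear_minor: tuple[float, float] | None = None
    overlap_allowance: float = 0.6  # min center distance / mean major axis
    background: str = "cluttered"  # {"plain", "cluttered"}
    clutter_strokes: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3, 4):
            raise ValueError("level must be 1..4")
        if self.background not in ("plain", "cluttered"):
            raise ValueError("background must be 'plain' or 'cluttered'")

    @property
    def scale(self) -> float:
        h, w = self.image_size
        return math.sqrt(h * w) / _REFERENCE_SIZE

    def resolved_counts(self) -> tuple[int, int]:
        if self.count_range is not None:
            return self.count_range
        return LEVEL_COUNTS[self.level]

    def resolved_axes(self) -> tuple[tuple[float, float], tuple[float, float]]:
        # a mature wheat ear spans roughly 10-15% of a 1024^2 field tile
        major = self.ear_major or (96.0 * self.scale, 150.0 * self.scale)
        minor = self.ear_minor or (28.0 * self.scale, 44.0 * self.scale)
        return major, minor


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) float64 in [0, 1]
    annotations: tuple[PolygonAnnotation, ...]
    centers: TargetCenters
    level: int
    seed: int

    @property
    def count(self) -> int:
        return len(self.annotations)


def _ellipse_polygon(cx, cy, a, b, theta, n_vertices=16) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ct, st = math.cos(theta), math.sin(theta)
    return np.stack([cx + ct * x - st * y, cy + st * x + ct * y], axis=1)


def _paint_background(h, w, config: SceneConfig, rng) -> np.ndarray:
    # vegetation: green base with low-frequency mottling and pixel noise
    base = np.array([0.18, 0.32, 0.10])
    img = np.tile(base, (h, w, 1))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(3):
        fy, fx = rng.uniform(1.0, 4.0, 2)
        phase = rng.uniform(0, 2 * math.pi, 2)
        wave = 0.04 * np.sin(2 * math.pi * fy * yy / h + phase[0]) \
             * np.cos(2 * math.pi * fx * xx / w + phase[1])
        img[..., 1] += wave
        img[..., 0] += 0.3 * wave
    img += rng.normal(0.0, 0.02, size=(h, w, 3))
    if config.background == "cluttered":
        from skimage.draw import polygon as draw_polygon

        n_strokes = config.clutter_strokes
        if n_strokes is None:
            n_strokes = 20
        major, minor = config.resolved_axes()
        for _ in range(n_strokes):
            cx = rng.uniform(0, w)
            cy = rng.uniform(0, h)
            length = rng.uniform(major[0], 2.5 * major[1])
            width = rng.uniform(0.2 * minor[0], 0.6 * minor[0])
            theta = rng.uniform(0, math.pi)
            verts = _ellipse_polygon(cx, cy, length / 2, width / 2, theta, 12)
            rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=(h, w))
            # leaf-like stroke in an ear-similar (dull golden-green) hue
            hue = np.array([
                rng.uniform(0.30, 0.45),
                rng.uniform(0.32, 0.42),
                rng.uniform(0.08, 0.16),
            ])
            img[rr, cc] = 0.6 * img[rr, cc] + 0.4 * hue
    return img


def _paint_ear(img, cx, cy, a, b, theta, rng) -> None:
    from skimage.draw import polygon as draw_polygon

    h, w = img.shape[:2]
    verts = _ellipse_polygon(cx, cy, a, b, theta, 32)
    rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=(h, w))
    if len(rr) == 0:
        return
    brightness = rng.uniform(0.85, 1.15)
    base = np.array([0.72, 0.60, 0.28]) * brightness  # golden
    # spikelet texture: periodic modulation along the major axis
    ct, st = math.cos(theta), math.sin(theta)
    axial = (cc - cx) * ct + (rr - cy) * st
    period = rng.uniform(3.0, 5.0)
    ripple = 0.12 * np.sin(2 * math.pi * axial / period)
    color = np.clip(base[None, :] * (1.0 + ripple[:, None]), 0, 1)
    img[rr, cc] = color
    # awn fringe: sparse bright speckles just outside the tip
    n_awns = rng.integers(6, 14)
    tip = np.array([cx + ct * a, cy + st * a])
    for _ in range(n_awns):
        ang = theta + rng.normal(0.0, 0.4)
        r = rng.uniform(0.1 * a, 0.5 * a)
        px = int(tip[0] + r * math.cos(ang))
        py = int(tip[1] + r * math.sin(ang))
        if 0 <= px < w and 0 <= py < h:
            img[py, px] = np.clip(base * 1.2, 0, 1)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render one scene with polygon ground truth (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    lo, hi = config.resolved_counts()
    n_ears = int(rng.integers(lo, hi + 1))
    (maj_lo, maj_hi), (min_lo, min_hi) = config.resolved_axes()

    img = _paint_background(h, w, config, rng)

    # rejection-sample centers with a level-dependent separation; higher
    # levels tolerate more overlap
    min_sep = config.overlap_allowance * (maj_lo + maj_hi) / 2 \
        * (1.0 - 0.15 * (config.level - 1))
    margin = min_hi  # keep centers >= minor-axis inside the frame
    centers: list[tuple[float, float]] = []
    max_tries = 200 * n_ears + 1000
    tries = 0
    while len(centers) < n_ears:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_ears} ears after {max_tries} tries; "
                "lower the count or enlarge the image"
            )
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        if all((cx - x) ** 2 + (cy - y) ** 2 >= min_sep ** 2
               for x, y in centers):
            centers.append((cx, cy))

    annotations = []
    for i, (cx, cy) in enumerate(centers):
        a = rng.uniform(maj_lo, maj_hi) / 2
        b = rng.uniform(min_lo, min_hi) / 2
        theta = rng.uniform(0, math.pi)
        _paint_ear(img, cx, cy, a, b, theta, rng)
        verts = _ellipse_polygon(cx, cy, a, b, theta, 16)
        verts[:, 0] = np.clip(verts[:, 0], 0, w - 1e-6)
        verts[:, 1] = np.clip(verts[:, 1], 0, h - 1e-6)
        annotations.append(PolygonAnnotation(
            annotation_id=i + 1, image_id=config.seed,
            vertices=tuple(map(tuple, verts)),
        ))
    img = np.clip(img, 0.0, 1.0)
    return SyntheticScene(
        image=img,
        annotations=tuple(annotations),
        centers=TargetCenters(tuple(centers)),
        level=config.level,
        seed=config.seed,
    )


def generate_dataset(n_per_level: int, base: SceneConfig, seed: int,
                     out_dir: str | Path | None = None) -> dict:
    """Generate ``4 * n_per_level`` scenes plus a COCO document + manifest.

    Returns ``{"scenes", "coco", "manifest"}``; when ``out_dir`` is given,
    writes PNG images, ``coco.json`` and ``manifest.json`` there.
    """
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    scenes: list[SyntheticScene] = []
    images: list[ImageRecord] = []
    annotations: list[PolygonAnnotation] = []
    manifest = {"seed": seed, "n_per_level": n_per_level, "scenes": []}
    next_ann = 1
    for level in (1, 2, 3, 4):
        for j in range(n_per_level):
            scene_seed = seed * 100003 + level * 1009 + j
            cfg = replace(base, level=level, seed=scene_seed)
            scene = generate_scene(cfg)
            image_id = len(images) + 1
            h, w = scene.image.shape[:2]
            file_name = f"scene_L{level}_{j:03d}.png"
            images.append(ImageRecord(image_id=image_id, file_name=file_name,
                                      width=w, height=h))
            for ann in scene.annotations:
                annotations.append(replace(
                    ann, annotation_id=next_ann, image_id=image_id))
                next_ann += 1
            scenes.append(scene)
            manifest["scenes"].append({
                "image_id": image_id, "file_name": file_name,
                "level": level, "seed": scene_seed, "count": scene.count,
            })
    coco = to_coco(images, annotations)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from PIL import Image as PILImage

        for scene, record in zip(scenes, images):
            arr = (scene.image * 255).astype(np.uint8)
            PILImage.fromarray(arr).save(out / record.file_name)
        (out / "coco.json").write_text(json.dumps(coco))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"scenes": scenes, "coco": coco, "manifest": manifest}
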