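"""Polygon annotation I/O: labelme and COCO documents, centroids, tiling, splits.

Wheat-ear instances are annotated as polygons (one outline per ear) in
labelme JSON; datasets are stored and exchanged as COCO instance documents
with a single category ``"ear"``.  Coordinates are 0-based continuous pixel
coordinates, origin top-left, x rightward, y downward; bounding boxes are
half-open ``[x, x+w) x [y, y+h)`` as in COCO practice.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.geometry import box as _shapely_box

logger = logging.getLogger(__name__)

EAR_CATEGORY_ID = 1
EAR_CATEGORY_NAME = "ear"


@dataclass(frozen=True)
class ImageRecord:
    """One image in a dataset."""

    image_id: int
    file_name: str
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"image {self.image_id}: non-positive size {self.width}x{self.height}"
            )


@dataclass(frozen=True)
class PolygonAnnotation:
    """One wheat-ear instance outline in image pixel coordinates.

    ``bbox`` is ``(x_min, y_min, width, height)``; ``area`` is the polygon
    (shoelace) area in pixels squared.  Both are derived from ``vertices``
    on construction when not supplied.
    """

    annotation_id: int
    image_id: int
    vertices: tuple[tuple[float, float], ...]
    category: str = EAR_CATEGORY_NAME
    bbox: tuple[float, float, float, float] = field(default=None)  # type: ignore[assignment]
    area: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValueError(
                f"annotation {self.annotation_id}: polygon needs >= 3 vertices, got {len(verts)}"
            )
        object.__setattr__(self, "vertices", verts)
        if self.bbox is None:
            object.__setattr__(self, "bbox", polygon_bbox(verts))
        if self.area is None:
            object.__setattr__(self, "area", polygon_area(verts))

    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass(frozen=True)
class DatasetSplit:
    """Train/val/test image-id partition in the 8:1:1 ratio."""

    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]
    seed: int


def polygon_area(vertices) -> float:
    """Unsigned shoelace area of a simple polygon."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def polygon_bbox(vertices) -> tuple[float, float, float, float]:
    v = np.asarray(vertices, dtype=float)
    x0, y0 = v.min(axis=0)
    x1, y1 = v.max(axis=0)
    return (float(x0), float(y0), float(x1 - x0), float(y1 - y0))


def instance_center(annotation: PolygonAnnotation) -> tuple[float, float]:
    """Area-weighted centroid of the instance polygon.

    The centroid (not the bbox center) defines the target center used for
    density-map generation; it is invariant to how densely the outline was
    clicked and to the starting vertex.
    """
    poly = annotation.shapely()
    if poly.area <= 0:
        raise ValueError(f"annotation {annotation.annotation_id}: zero-area polygon")
    c = poly.centroid
    return (float(c.x), float(c.y))


def parse_labelme(document: str) -> tuple[ImageRecord, list[PolygonAnnotation]]:
    """Parse one labelme JSON document into an image record plus polygons.

    Non-polygon shapes are skipped with a warning; a "polygon" with fewer
    than 3 points is a validation error naming the shape index.
    """
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed labelme JSON: {exc}") from exc
    try:
        width = int(doc["imageWidth"])
        height = int(doc["imageHeight"])
        shapes = doc["shapes"]
    except KeyError as exc:
        raise ValueError(f"labelme document missing key {exc}") from exc
    image = ImageRecord(
        image_id=int(doc.get("imageId", 0)),
        file_name=str(doc.get("imagePath", "")),
        width=width,
        height=height,
    )
    annotations: list[PolygonAnnotation] = []
    for idx, shape in enumerate(shapes):
        if shape.get("shape_type", "polygon") != "polygon":
            logger.warning(
                "skipping non-polygon shape %d of type %r", idx, shape.get("shape_type")
            )
            continue
        points = shape["points"]
        if len(points) < 3:
            raise ValueError(f"shape {idx}: polygon has {len(points)} points (< 3)")
        annotations.append(
            PolygonAnnotation(
                annotation_id=len(annotations) + 1,
                image_id=image.image_id,
                category=str(shape.get("label", EAR_CATEGORY_NAME)),
                vertices=tuple((float(x), float(y)) for x, y in points),
            )
        )
    return image, annotations


def to_coco(
    images: list[ImageRecord], annotations: list[PolygonAnnotation]
) -> dict:
    """Serialize records into a COCO instance document (polygon segmentation)."""
    known = {im.image_id for im in images}
    for ann in annotations:
        if ann.image_id not in known:
            raise ValueError(
                f"annotation {ann.annotation_id} references unknown image {ann.image_id}"
            )
    return {
        "images": [
            {
                "id": im.image_id,
                "file_name": im.file_name,
                "width": im.width,
                "height": im.height,
            }
            for im in images
        ],
        "annotations": [
            {
                "id": ann.annotation_id,
                "image_id": ann.image_id,
                "category_id": EAR_CATEGORY_ID,
                "segmentation": [
                    [coord for xy in ann.vertices for coord in xy]
                ],
                "bbox": list(ann.bbox),
                "area": ann.area,
                "iscrowd": 0,
            }
            for ann in annotations
        ],
        "categories": [{"id": EAR_CATEGORY_ID, "name": EAR_CATEGORY_NAME}],
    }


def parse_coco(document) -> tuple[list[ImageRecord], list[PolygonAnnotation]]:
    """Parse a COCO instance document (inverse of :func:`to_coco`).

    Multi-part polygon segmentations yield one :class:`PolygonAnnotation`
    per part sharing the annotation metadata.  RLE segmentations are not
    supported.
    """
    if isinstance(document, (str, bytes)):
        document = json.loads(document)
    try:
        image_entries = document["images"]
        ann_entries = document["annotations"]
        document["categories"]
    except KeyError as exc:
        raise ValueError(f"COCO document missing key {exc}") from exc
    images = [
        ImageRecord(
            image_id=int(e["id"]),
            file_name=str(e.get("file_name", "")),
            width=int(e["width"]),
            height=int(e["height"]),
        )
        for e in image_entries
    ]
    categories = {
        int(c["id"]): str(c["name"]) for c in document["categories"]
    }
    annotations: list[PolygonAnnotation] = []
    for e in ann_entries:
        seg = e["segmentation"]
        if isinstance(seg, dict) or (seg and isinstance(seg[0], dict)):
            raise ValueError(
                f"annotation {e.get('id')}: RLE segmentation is not supported"
            )
        for part in seg:
            coords = tuple(
                (float(part[i]), float(part[i + 1])) for i in range(0, len(part), 2)
            )
            annotations.append(
                PolygonAnnotation(
                    annotation_id=int(e["id"]),
                    image_id=int(e["image_id"]),
                    category=categories.get(int(e.get("category_id", EAR_CATEGORY_ID)),
                                            EAR_CATEGORY_NAME),
                    vertices=coords,
                )
            )
    return images, annotations


def tile_image(
    image: np.ndarray,
    tile: tuple[int, int],
    annotations: list[PolygonAnnotation] | None = None,
    min_area_fraction: float = 0.25,
) -> list[dict]:
    """Cut an image into a non-overlapping grid of ``tile`` = (W, H) tiles.

    Tiling starts at the top-left; a trailing remainder narrower than a tile
    is discarded.  When ``annotations`` are given, each polygon is clipped to
    the tile (offset subtracted); clips retaining less than
    ``min_area_fraction`` of the original area are dropped to avoid sliver
    ground truth.

    Returns a list of ``{"image", "offset", "annotations"}`` dicts, with
    ``offset`` = (x, y) of the tile's top-left corner in the source image.
    """
    tw, th = int(tile[0]), int(tile[1])
    ih, iw = image.shape[:2]
    if tw > iw or th > ih:
        raise ValueError(f"tile {tw}x{th} larger than image {iw}x{ih}")
    tiles = []
    for row in range(ih // th):
        for col in range(iw // tw):
            ox, oy = col * tw, row * th
            sub = image[oy : oy + th, ox : ox + tw]
            kept: list[PolygonAnnotation] = []
            if annotations:
                window = _shapely_box(ox, oy, ox + tw, oy + th)
                for ann in annotations:
                    clipped = ann.shapely().intersection(window)
                    if clipped.is_empty:
                        continue
                    if clipped.geom_type == "MultiPolygon":
                        clipped = max(clipped.geoms, key=lambda g: g.area)
                    if clipped.geom_type != "Polygon" or clipped.area <= 0:
                        continue
                    if clipped.area < min_area_fraction * ann.area:
                        continue
                    verts = tuple(
                        (x - ox, y - oy) for x, y in clipped.exterior.coords[:-1]
                    )
                    if len(verts) < 3:
                        continue
                    kept.append(replace(ann, vertices=verts, bbox=None, area=None))
            tiles.append({"image": sub, "offset": (ox, oy), "annotations": kept})
    return tiles


def split_dataset(image_ids: list[int], seed: int) -> DatasetSplit:
    """Deterministic 8:1:1 train/val/test split by image id.

    Sizes are ``(round(0.8 n), round(0.1 n), remainder)``.  Splitting is by
    image (never by tile) so tiles of one photograph cannot leak across
    sets.
    """
    ids = list(image_ids)
    n = len(ids)
    if n < 10:
        raise ValueError(f"need >= 10 images for an 8:1:1 split, got {n}")
    if len(set(ids)) != n:
        raise ValueError("duplicate image ids")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    n_train = round(0.8 * n)
    n_val = round(0.1 * n)
    return DatasetSplit(
        train=tuple(order[:n_train]),
        val=tuple(order[n_train : n_train + n_val]),
        test=tuple(order[n_train + n_val :]),
        seed=seed,
    )


def rasterize_polygon(
    vertices, shape: tuple[int, int], scale: float = 1.0
) -> np.ndarray:
    """Rasterize a polygon to a binary (H, W) mask, optionally rescaled."""
    from skimage.draw import polygon as _draw_polygon

    v = np.asarray(vertices, dtype=float) * scale
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _draw_polygon(v[:, 1], v[:, 0], shape=shape)
    mask[rr, cc] = True
    return mask
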