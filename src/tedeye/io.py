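"""Reading and writing the on-disk formats.

Images are 8-bit RGB PNG; label masks are single-channel indexed-palette PNG
whose pixel values are the class indices of the declared ontology; manifests
are plain CSV.  A LabelMe-style polygon-JSON rasterizer is provided so real
annotations can substitute for synthetic masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .types import CLASS_INDEX, LabelMask, ONTOLOGIES

#: Display palette for mask PNGs (index -> RGB); indices are the classes.
_PALETTE = [
    (0, 0, 0),        # background
    (230, 230, 230),  # sclera / left eye
    (70, 130, 180),   # iris / right eye
    (220, 60, 60),    # pupil / scale
    (240, 170, 60),   # lcp
]


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_mask(path, mask: LabelMask) -> None:
    im = Image.fromarray(mask.grid.astype(np.uint8), mode="P")
    palette = []
    for rgb in _PALETTE:
        palette.extend(rgb)
    im.putpalette(palette + [0] * (768 - len(palette)))
    im.save(path)


def read_mask(path, ontology: str) -> LabelMask:
    im = Image.open(path)
    if im.mode not in ("P", "L"):
        raise ValueError(f"mask {path} must be indexed or single-channel, got {im.mode}")
    mask = LabelMask(grid=np.asarray(im, dtype=np.uint8), ontology=ontology)
    mask.validate()
    return mask


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def rasterize_labelme(annotation: dict | str | Path, ontology: str,
                      image_size: tuple[int, int] | None = None) -> LabelMask:
    """Rasterize a LabelMe polygon annotation into a :class:`LabelMask`.

    ``annotation`` is a parsed LabelMe dict or a path to its JSON file.
    Shape labels must name classes of the ontology (e.g. ``sclera``,
    ``iris``, ``pupil``, ``lcp``); polygons are filled in file order except
    that higher class indices overwrite lower ones, so a pupil polygon drawn
    inside an iris polygon wins.  LabelMe points are (x, y) = (col, row).
    """
    if not isinstance(annotation, dict):
        with open(annotation) as fh:
            annotation = json.load(fh)
    if image_size is None:
        image_size = (annotation["imageHeight"], annotation["imageWidth"])
    rows, cols = image_size
    index = CLASS_INDEX[ontology]

    shapes = []
    for shape in annotation.get("shapes", []):
        label = shape["label"]
        if label not in index:
            raise ValueError(
                f"label {label!r} is not a class of ontology {ontology!r}; "
                f"expected one of {sorted(index)}"
            )
        if shape.get("shape_type", "polygon") != "polygon":
            raise ValueError(f"unsupported shape_type {shape['shape_type']!r}")
        shapes.append((index[label], shape["points"]))

    grid = np.zeros((rows, cols), dtype=np.uint8)
    for cls, points in sorted(shapes, key=lambda t: t[0]):
        layer = Image.new("L", (cols, rows), 0)
        ImageDraw.Draw(layer).polygon(
            [(float(x), float(y)) for x, y in points], fill=1
        )
        grid[np.asarray(layer, dtype=bool)] = cls
    mask = LabelMask(grid=grid, ontology=ontology)
    mask.validate()
    return mask


def mask_to_labelme_classes(ontology: str) -> list[str]:
    """Class names a LabelMe annotator should use for this ontology."""
    return [name for idx, name in sorted(ONTOLOGIES[ontology].items()) if idx > 0]
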