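"""Mask-guided cropping of individual seeds and class-folder dataset handling.

Non-touching seeds are cropped straight from the enhanced scene at their
located boxes. Touching clusters are masked at their box, separated
(erosion or watershed), the eroded boxes are compensated by the kernel
radius, and each part is cropped. Every crop is padded to a centered square
with background-colored margins and resized to 227x227 px, the input size
of the downstream classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from PIL import Image
from numpy.typing import NDArray

from .enhance import RetinexParams, msrcr
from .errors import DatasetError, DegenerateHistogramError, GeometryError
from .segment import (
    ContactRule,
    SeedBox,
    SeparationConfig,
    binarize,
    classify_touching,
    locate_seeds,
    separate_eop,
    separate_wa,
)

__all__ = [
    "SeedCrop",
    "DatasetLayout",
    "CLASS_FOLDERS",
    "crop_seed",
    "erosion_compensation",
    "run_pipeline",
    "scan_dataset",
]

logger = logging.getLogger(__name__)

#: output side of every individual-seed crop, in px
CROP_SIDE = 227

#: the five quality classes of the class-folder dataset layout
CLASS_FOLDERS = ("Intact", "Immature", "Skin-damaged", "Spotted", "Broken")

_IMAGE_SUFFIXES = {".bmp", ".jpg", ".jpeg", ".png"}

#: components smaller than this many px are treated as specks before the
#: scene-median seed size is known
_SPECK_AREA = 16

#: fraction of the median component area below which a component is debris
_MIN_AREA_FRACTION = 0.1


@dataclass(frozen=True)
class SeedCrop:
    """One individual-seed image with provenance.

    ``box`` is the located box before any kernel-radius compensation;
    ``crop_box`` is the region actually cropped (post-compensation, before
    square padding). For non-touching seeds the two coincide.
    """

    pixels: NDArray[np.uint8]
    scene_id: str
    box: SeedBox
    crop_box: SeedBox
    separated_by: str = "none"  # none | EOP | WA


@dataclass(frozen=True)
class DatasetLayout:
    """Counts of image files per immediate subfolder of a dataset root."""

    root: Path
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def crop_seed(
    enhanced: NDArray[np.uint8],
    box: SeedBox,
    pad: int = 0,
    out_side: int = CROP_SIDE,
    bg_color: tuple[int, int, int] | NDArray | None = None,
) -> NDArray[np.uint8]:
    """Crop a box out of the scene, square-pad it, and resize to out_side.

    The box is expanded by ``pad`` px on each side (clamped at scene
    borders), embedded centered in a square canvas filled with ``bg_color``
    (default: the scene's median color, which on seed scenes is the dark
    background), and resized with area averaging when shrinking or bilinear
    interpolation when enlarging.
    """
    H, W = enhanced.shape[:2]
    if box.w < 1 or box.h < 1:
        raise GeometryError(f"degenerate box {box}")
    if box.x < 0 or box.y < 0 or box.x + box.w > W or box.y + box.h > H:
        raise GeometryError(f"box {box} outside {W}x{H} scene")
    if pad < 0:
        raise GeometryError("pad must be >= 0")
    x0 = max(0, box.x - pad)
    y0 = max(0, box.y - pad)
    x1 = min(W, box.x + box.w + pad)
    y1 = min(H, box.y + box.h + pad)
    region = enhanced[y0:y1, x0:x1]
    rh, rw = region.shape[:2]

    side = max(rh, rw)
    if bg_color is None:
        bg_color = np.median(enhanced.reshape(-1, 3), axis=0)
    canvas = np.empty((side, side, 3), dtype=np.uint8)
    canvas[:] = np.asarray(np.rint(np.asarray(bg_color, dtype=float)), dtype=np.uint8)
    oy = (side - rh) // 2
    ox = (side - rw) // 2
    canvas[oy : oy + rh, ox : ox + rw] = region

    if side == out_side:
        return canvas
    resample = Image.Resampling.BOX if side > out_side else Image.Resampling.BILINEAR
    img = Image.fromarray(canvas).resize((out_side, out_side), resample)
    return np.asarray(img, dtype=np.uint8)


def erosion_compensation(
    box: SeedBox, kernel: int, bounds: tuple[int, int] | None = None
) -> SeedBox:
    """Expand an eroded-geometry box by the kernel radius on each side.

    Erosion with a k x k square shrinks every object by (k-1)/2 px per
    side, so expanding the relocated box by the same amount recovers the
    pre-erosion extent (clamped to the scene ``bounds`` = (height, width)).
    """
    r = (kernel - 1) // 2
    x0 = box.x - r
    y0 = box.y - r
    x1 = box.x + box.w + r
    y1 = box.y + box.h + r
    if bounds is not None:
        H, W = bounds
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(W, x1), min(H, y1)
    return replace(box, x=x0, y=y0, w=x1 - x0, h=y1 - y0)


def _median_background(
    enhanced: NDArray[np.uint8], mask: NDArray[np.bool_]
) -> NDArray[np.float64]:
    bg = enhanced[~mask]
    if bg.size == 0:
        return np.zeros(3)
    return np.median(bg.reshape(-1, 3), axis=0)


def run_pipeline(
    scene: NDArray[np.uint8],
    retinex: RetinexParams | None = None,
    rule: ContactRule | None = None,
    sep: SeparationConfig | None = None,
    *,
    scene_id: str = "scene",
    pad: int = 2,
    enhanced: NDArray[np.uint8] | None = None,
    crop_from_raw: bool = False,
) -> list[SeedCrop]:
    """Full scene -> individual-seed-crops pipeline.

    enhance -> binarize -> locate -> contact judgment; non-touching boxes
    are cropped directly, touching clusters are masked at their box,
    separated by ``sep.method`` (erosion boxes are kernel-compensated), and
    cropped. Crops are taken from the enhanced scene unless
    ``crop_from_raw`` is set. A precomputed ``enhanced`` image may be
    passed to amortize enhancement across separation configs.

    Returns all crops with provenance, in deterministic row-major box
    order. A blank (single-intensity) scene yields an empty list with a
    logged warning rather than an error.
    """
    retinex = retinex or RetinexParams()
    rule = rule or ContactRule()
    sep = sep or SeparationConfig()
    if enhanced is None:
        enhanced = msrcr(scene, retinex)
    try:
        mask = binarize(enhanced)
    except DegenerateHistogramError:
        logger.warning("scene %s is single-intensity after enhancement; no seeds", scene_id)
        return []

    boxes = locate_seeds(mask, min_area=_SPECK_AREA)
    if not boxes:
        return []
    median_area = float(np.median([b.area for b in boxes]))
    boxes = [b for b in boxes if b.area >= _MIN_AREA_FRACTION * median_area]
    boxes = classify_touching(boxes, rule)

    source = scene if crop_from_raw else enhanced
    bg = _median_background(source, mask)

    wa_min_distance = sep.wa_min_distance
    if sep.method == "WA" and wa_min_distance is None:
        singles = [b for b in boxes if not b.touching] or boxes
        median_side = float(np.median([(b.w + b.h) / 2.0 for b in singles]))
        wa_min_distance = max(1.0, 0.5 * median_side)

    # label once so each touching box can be masked to its own component:
    # a cluster's rectangle may clip corners of neighboring seeds, and those
    # alien fragments must not survive separation as spurious outputs
    labels, _ = ndi.label(mask, structure=np.ones((3, 3), bool))

    crops: list[SeedCrop] = []

    def emit(located: SeedBox, crop_box: SeedBox, separated_by: str) -> None:
        crops.append(
            SeedCrop(
                pixels=crop_seed(source, crop_box, pad=pad, bg_color=bg),
                scene_id=scene_id,
                box=located,
                crop_box=crop_box,
                separated_by=separated_by,
            )
        )

    for b in boxes:
        if not b.touching:
            emit(b, b, "none")
            continue
        cluster = np.zeros_like(mask)
        region = (slice(b.y, b.y + b.h), slice(b.x, b.x + b.w))
        cluster[region] = labels[region] == b.component_id
        if sep.method == "EOP":
            parts = separate_eop(cluster, sep, min_area=_SPECK_AREA)
            for p in parts:
                if p.unseparated:
                    emit(p, p, "EOP")
                else:
                    emit(p, erosion_compensation(p, sep.kernel, mask.shape), "EOP")
        else:
            parts = separate_wa(cluster, replace(sep, wa_min_distance=wa_min_distance))
            for p in parts:
                emit(p, p, "WA")
    return crops


def scan_dataset(root: Path | str) -> DatasetLayout:
    """Count image files (BMP/JPG/PNG) per immediate subfolder of root."""
    root = Path(root)
    if not root.is_dir():
        raise DatasetError(f"dataset root {root} does not exist")
    counts: dict[str, int] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        counts[sub.name] = sum(
            1 for f in sub.iterdir() if f.is_file() and f.suffix.lower() in _IMAGE_SUFFIXES
        )
    return DatasetLayout(root=root, counts=counts)
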