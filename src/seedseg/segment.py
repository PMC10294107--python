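"""Binarization, seed localization, contact judgment and touching-seed separation.

The enhanced scene is thresholded with Otsu's method, connected foreground
components are located by their tight axis-aligned minimum bounding
rectangles (MBRs), and MBR size relative to the scene's typical single-seed
size decides which components are merged clusters of physically touching
seeds. Clusters are split either by erosion with a square kernel (EOP, which
removes the thin "tiny contact" bridges between seeds) or by marker-based
watershed on the distance transform (WA).

Masks are plain 2-D boolean numpy arrays (``True`` = seed pixel), the same
shape as their source scene.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import scipy.ndimage as ndi
from numpy.typing import NDArray
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .errors import (
    DegenerateHistogramError,
    EmptyReferenceError,
    ParameterError,
)

__all__ = [
    "SeedBox",
    "ContactRule",
    "SeparationConfig",
    "otsu_threshold",
    "binarize",
    "locate_seeds",
    "classify_touching",
    "erode",
    "separate_eop",
    "separate_wa",
]

# 8-connected foreground
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)

#: ITU-R 601 luma weights used for RGB -> grayscale conversion
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class SeedBox:
    """Tight axis-aligned bounding box of one connected component.

    Coordinates are 0-based with x = column and y = row; the box is the
    half-open region ``[x, x+w) x [y, y+h)``.
    """

    x: int
    y: int
    w: int
    h: int
    component_id: int = 0
    touching: bool = False
    #: pixel count of the component (not the box area)
    area: int = 0
    #: set when a touching cluster could not be separated and is passed
    #: through whole rather than silently dropped
    unseparated: bool = False

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ParameterError(f"box sides must be >= 1, got {self.w}x{self.h}")

    @property
    def box_area(self) -> int:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) of the box."""
        return (self.x + (self.w - 1) / 2.0, self.y + (self.h - 1) / 2.0)


@dataclass(frozen=True)
class ContactRule:
    """MBR-size rule deciding whether a component is a touching cluster.

    A box is flagged touching iff its box area exceeds ``area_ratio`` times
    the reference single-seed box area, or its longer side exceeds
    ``side_ratio`` times the square root of the reference area. The
    reference is the scene-median box area by default ("median-of-scene"),
    on the grounds that touching clusters are a minority; an explicit
    calibrated area may be given instead.
    """

    area_ratio: float = 1.5
    side_ratio: float = 1.4
    reference: Literal["median-of-scene"] | float = "median-of-scene"

    def __post_init__(self) -> None:
        if self.area_ratio <= 1 or self.side_ratio <= 1:
            raise ParameterError("contact ratios must be > 1")
        if not isinstance(self.reference, str) and self.reference <= 0:
            raise ParameterError("explicit reference area must be > 0")


@dataclass(frozen=True)
class SeparationConfig:
    """How to split a touching cluster: square-kernel erosion or watershed."""

    method: Literal["EOP", "WA"] = "EOP"
    kernel: int = 13
    #: minimum marker separation for watershed, in px; None = derived from
    #: the scene (half the median seed side)
    wa_min_distance: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("EOP", "WA"):
            raise ParameterError(f"method must be EOP or WA, got {self.method!r}")
        if self.kernel < 3 or self.kernel % 2 == 0:
            raise ParameterError(f"kernel must be odd and >= 3, got {self.kernel}")
        if self.wa_min_distance is not None and self.wa_min_distance <= 0:
            raise ParameterError("wa_min_distance must be > 0")


def otsu_threshold(histogram: Sequence[int] | NDArray) -> int:
    """Threshold maximizing between-class variance of a 256-bin histogram.

    Returns t in [0, 255]; pixels with intensity <= t form the background
    class. Ties are broken toward the lowest threshold.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ParameterError(f"expected a 256-bin histogram, got shape {hist.shape}")
    if np.any(hist < 0):
        raise ParameterError("histogram counts must be non-negative")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied bins")

    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    omega0 = np.cumsum(p)                # class probability of {0..t}
    mu = np.cumsum(p * levels)           # first moment of {0..t}
    mu_total = mu[-1]
    omega1 = 1.0 - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    sigma_b = np.full(256, -np.inf)
    sigma_b[valid] = (mu_total * omega0[valid] - mu[valid]) ** 2 / (
        omega0[valid] * omega1[valid]
    )
    return int(np.argmax(sigma_b))


def to_grayscale(scene: NDArray[np.uint8]) -> NDArray[np.uint8]:
    """RGB -> grayscale with ITU-R 601 luma weights, rounded to uint8."""
    img = np.asarray(scene, dtype=np.float64)
    gray = (
        LUMA_WEIGHTS[0] * img[:, :, 0]
        + LUMA_WEIGHTS[1] * img[:, :, 1]
        + LUMA_WEIGHTS[2] * img[:, :, 2]
    )
    return np.floor(gray + 0.5).astype(np.uint8)


def binarize(
    enhanced: NDArray[np.uint8],
    polarity: Literal["bright", "dark"] = "bright",
) -> NDArray[np.bool_]:
    """Otsu-threshold an RGB scene into a foreground mask.

    With the default ``bright`` polarity, foreground = pixels above the
    Otsu threshold (seeds are brighter than the background). ``dark``
    polarity inverts the grayscale first, so inverting the scene and
    flipping the polarity yields the identical mask.
    """
    gray = to_grayscale(enhanced)
    if polarity == "dark":
        gray = (255 - gray.astype(np.int16)).astype(np.uint8)
    hist = np.bincount(gray.ravel(), minlength=256)
    t = otsu_threshold(hist)
    return gray > t


def locate_seeds(mask: NDArray[np.bool_], min_area: float = 0) -> list[SeedBox]:
    """Tight bounding boxes of 8-connected components with area >= min_area.

    Boxes are returned in deterministic row-major order of their top-left
    corner (by y, then x).
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=_STRUCTURE_8)
    if n == 0:
        return []
    areas = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    boxes = []
    for lab, (sl_y, sl_x) in enumerate(ndi.find_objects(labels), start=1):
        area = int(areas[lab - 1])
        if area < min_area:
            continue
        boxes.append(
            SeedBox(
                x=sl_x.start,
                y=sl_y.start,
                w=sl_x.stop - sl_x.start,
                h=sl_y.stop - sl_y.start,
                component_id=lab,
                area=area,
            )
        )
    boxes.sort(key=lambda b: (b.y, b.x))
    return boxes


def classify_touching(boxes: Sequence[SeedBox], rule: ContactRule | None = None) -> list[SeedBox]:
    """Return copies of the boxes with their ``touching`` flags set."""
    rule = rule or ContactRule()
    if rule.reference == "median-of-scene":
        if not boxes:
            raise EmptyReferenceError(
                "median-of-scene contact reference needs at least one box"
            )
        reference = float(np.median([b.box_area for b in boxes]))
    else:
        reference = float(rule.reference)
    side_limit = rule.side_ratio * np.sqrt(reference)
    out = []
    for b in boxes:
        flag = b.box_area > rule.area_ratio * reference or max(b.w, b.h) > side_limit
        out.append(replace(b, touching=bool(flag)))
    return out


def erode(mask: NDArray[np.bool_], kernel: int) -> NDArray[np.bool_]:
    """Morphological erosion with a filled square structuring element.

    A foreground pixel survives iff its whole kernel x kernel neighborhood
    is foreground; pixels outside the image count as background. Erosion is
    anti-extensive, and square-kernel erosions compose:
    ``erode(erode(m, k1), k2) == erode(m, k1 + k2 - 1)``.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ParameterError(f"kernel must be odd and >= 1, got {kernel}")
    mask = np.asarray(mask, dtype=bool)
    if kernel == 1:
        return mask.copy()
    structure = np.ones((kernel, kernel), dtype=bool)
    return ndi.binary_erosion(mask, structure=structure, border_value=0)


def _unseparated(cluster_mask: NDArray[np.bool_]) -> list[SeedBox]:
    return [replace(b, unseparated=True) for b in locate_seeds(cluster_mask, 0)]


def separate_eop(
    cluster_mask: NDArray[np.bool_],
    config: SeparationConfig,
    min_area: float = 0,
) -> list[SeedBox]:
    """Split a touching cluster by square-kernel erosion, then relocate.

    The returned boxes live in the eroded geometry; kernel-radius
    compensation is applied at crop time. If erosion wipes the cluster out
    entirely, the original cluster box is returned flagged ``unseparated``
    so no seed region is silently dropped.
    """
    eroded = erode(cluster_mask, config.kernel)
    boxes = locate_seeds(eroded, min_area)
    if not boxes:
        return _unseparated(cluster_mask)
    return boxes


def separate_wa(
    cluster_mask: NDArray[np.bool_],
    config: SeparationConfig,
) -> list[SeedBox]:
    """Split a touching cluster by marker-based watershed.

    Markers are local maxima of the Euclidean distance transform separated
    by at least ``config.wa_min_distance`` px; basins partition the cluster
    foreground exactly, and one box per basin is returned. With no markers
    the original cluster box is returned flagged ``unseparated``.
    """
    if config.wa_min_distance is None:
        raise ParameterError("separate_wa requires an explicit wa_min_distance")
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    dist = ndi.distance_transform_edt(cluster_mask)
    labels, _ = ndi.label(cluster_mask, structure=_STRUCTURE_8)
    coords = peak_local_max(
        dist,
        min_distance=max(1, int(round(config.wa_min_distance))),
        labels=labels,
        exclude_border=False,
    )
    if len(coords) == 0:
        return _unseparated(cluster_mask)
    markers = np.zeros(cluster_mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    basins = watershed(-dist, markers, mask=cluster_mask)
    boxes = []
    for lab, sl in enumerate(ndi.find_objects(basins), start=1):
        if sl is None:
            continue
        sl_y, sl_x = sl
        area = int(np.count_nonzero(basins[sl] == lab))
        boxes.append(
            SeedBox(
                x=sl_x.start,
                y=sl_y.start,
                w=sl_x.stop - sl_x.start,
                h=sl_y.stop - sl_y.start,
                component_id=lab,
                area=area,
            )
        )
    boxes.sort(key=lambda b: (b.y, b.x))
    return boxes
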