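"""Axis-aligned bounding boxes: the detection primitive.

Boxes live in 0-based pixel coordinates with a half-open convention:
a box of width w starting at column x0 covers columns x0 .. x0+w-1,
so areas are exact integer pixel counts when edges are integral.
Internally a box is stored by its center and size in float pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoundingBox",
    "iou",
    "bbox_encode",
    "bbox_decode",
    "nms",
    "box_mask",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle parameterized by center and size.

    Parameters
    ----------
    x_center, y_center : float
        Center coordinates in pixels (x = column, y = row).
    width, height : float
        Side lengths in pixels; must be positive.
    """

    x_center: float
    y_center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("box width and height must be positive")

    @property
    def x0(self) -> float:
        return self.x_center - self.width / 2.0

    @property
    def x1(self) -> float:
        return self.x_center + self.width / 2.0

    @property
    def y0(self) -> float:
        return self.y_center - self.height / 2.0

    @property
    def y1(self) -> float:
        return self.y_center + self.height / 2.0

    @property
    def area(self) -> float:
        return self.width * self.height

    @classmethod
    def from_corners(cls, x0: float, y0: float, x1: float, y1: float) -> "BoundingBox":
        """Build from half-open corner coordinates [x0, x1) x [y0, y1)."""
        return cls((x0 + x1) / 2.0, (y0 + y1) / 2.0, x1 - x0, y1 - y0)

    def clipped(self, shape: tuple[int, int]) -> "BoundingBox":
        """Clip to an (H, W) image frame, preserving at least 1 px of extent."""
        h, w = shape
        x0 = min(max(self.x0, 0.0), w - 1.0)
        y0 = min(max(self.y0, 0.0), h - 1.0)
        x1 = max(min(self.x1, float(w)), x0 + 1.0)
        y1 = max(min(self.y1, float(h)), y0 + 1.0)
        return BoundingBox.from_corners(x0, y0, x1, y1)

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.x_center, self.y_center, self.width, self.height)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes (continuous-area form).

    With integral half-open boxes this equals the pixel-counting IoU.
    """
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    if inter <= 0.0:
        return 0.0
    union = a.area + b.area - inter
    return inter / union


def bbox_encode(anchor: BoundingBox, proposal: BoundingBox) -> np.ndarray:
    """Parameterize the transform taking ``anchor`` onto ``proposal``.

    Returns the 4-vector z with center offsets scaled by the anchor size and
    plain (not log) size ratios:
    z1=(x_p-x_a)/w_a, z2=(y_p-y_a)/h_a, z3=w_p/w_a, z4=h_p/h_a.
    """
    if anchor.width <= 0 or anchor.height <= 0:
        raise ValueError("anchor must have positive size")
    return np.array(
        [
            (proposal.x_center - anchor.x_center) / anchor.width,
            (proposal.y_center - anchor.y_center) / anchor.height,
            proposal.width / anchor.width,
            proposal.height / anchor.height,
        ]
    )


def bbox_decode(
    anchor: BoundingBox,
    z: np.ndarray,
    image_shape: tuple[int, int] | None = None,
) -> BoundingBox:
    """Apply a regression vector z to an anchor box (inverse of bbox_encode).

    The refined box is (x_a + w_a z1, y_a + h_a z2, w_a z3, h_a z4),
    clipped to ``image_shape`` (H, W) when supplied.
    """
    z = np.asarray(z, dtype=float)
    if z.shape != (4,):
        raise ValueError("z must be a 4-vector")
    if z[2] <= 0 or z[3] <= 0:
        raise ValueError("size factors z3, z4 must be positive")
    box = BoundingBox(
        anchor.x_center + anchor.width * z[0],
        anchor.y_center + anchor.height * z[1],
        anchor.width * z[2],
        anchor.height * z[3],
    )
    if image_shape is not None:
        box = box.clipped(image_shape)
    return box


def nms(
    boxes: list[BoundingBox],
    scores: np.ndarray,
    threshold: float = 0.3,
) -> list[int]:
    """Greedy non-maximum suppression.

    Boxes are visited in descending score order; a box is suppressed when its
    IoU with an already-kept box exceeds ``threshold``. Ties in score are
    broken by the original index (stable). Returns kept indices in descending
    score order.
    """
    scores = np.asarray(scores, dtype=float)
    if len(boxes) != scores.size:
        raise ValueError("boxes and scores must have equal length")
    order = np.argsort(-scores, kind="stable")
    kept: list[int] = []
    for idx in order:
        i = int(idx)
        if all(iou(boxes[i], boxes[j]) <= threshold for j in kept):
            kept.append(i)
    return kept


def box_mask(box: BoundingBox, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a box to a boolean (H, W) mask by pixel-center inclusion."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    x0 = max(int(np.round(box.x0)), 0)
    y0 = max(int(np.round(box.y0)), 0)
    x1 = min(int(np.round(box.x1)), w)
    y1 = min(int(np.round(box.y1)), h)
    if x1 > x0 and y1 > y0:
        mask[y0:y1, x0:x1] = True
    return mask
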