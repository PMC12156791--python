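"""Placement and extraction of the standardized 10x30-pixel ROIs.

Two 10x30 windows are analyzed per implant (or control tooth): one mesial
and one distal, placed as close as possible to the first implant thread
(or to the cemento-enamel-junction line for control teeth) while clearing
an exclusion mask covering structures that would contaminate the texture —
implant threads, adjacent teeth, lamina dura, periodontal ligament,
alveolar crest and root surfaces.  Because all visits are pre-aligned to
the baseline, a single spec per patient-side is reused across every visit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .datatypes import Radiograph, RoiPatch, RoiSpec
from .errors import InputError, RoiPlacementError

__all__ = ["ImplantAnchor", "CejAnchor", "RoiPair", "place_rois", "extract"]


@dataclass(frozen=True)
class ImplantAnchor:
    """Implant landmark geometry: vertical axis column, lateral margin
    half-width (radius incl. threads) and the first-thread row."""

    axis_x: int
    first_thread_row: int
    margin_halfwidth: int

    def anchor_point(self, side: str) -> tuple[float, float]:
        """(x, y) of the implant margin at the first-thread row."""
        sign = -1 if side == "mesial" else 1
        return (self.axis_x + sign * self.margin_halfwidth, self.first_thread_row)

    anchor_name = "implant_first_thread"


@dataclass(frozen=True)
class CejAnchor:
    """Control-tooth landmark: the line joining the mesial and distal
    cemento-enamel junctions, stored as its two (x, y) endpoints."""

    mesial_xy: tuple[float, float]
    distal_xy: tuple[float, float]

    def anchor_point(self, side: str) -> tuple[float, float]:
        return self.mesial_xy if side == "mesial" else self.distal_xy

    anchor_name = "cej_line"


@dataclass
class RoiPair:
    """Result of :func:`place_rois`: one spec per side, with per-side errors
    (a failed side leaves the other usable)."""

    mesial: Optional[RoiSpec] = None
    distal: Optional[RoiSpec] = None
    errors: dict = None

    def __post_init__(self):
        if self.errors is None:
            self.errors = {}

    def require(self, side: str) -> RoiSpec:
        spec = getattr(self, side)
        if spec is None:
            raise self.errors[side]
        return spec


def _inner_edge_midpoint(x: int, y: int, width: int, height: int, side: str):
    """Midpoint of the ROI edge facing the implant axis (right edge for the
    mesial window, left edge for the distal)."""
    ex = x + width - 0.5 if side == "mesial" else x - 0.5
    return np.array([ex, y + (height - 1) / 2.0])


def _admissible(x, y, width, height, shape, blocked) -> bool:
    h, w = shape
    if x < 0 or y < 0 or x + width > w or y + height > h:
        return False
    return not blocked[y : y + height, x : x + width].any()


def place_rois(
    image: Radiograph,
    anchor,
    exclusion_mask: Optional[np.ndarray] = None,
    *,
    width: int = 10,
    height: int = 30,
    search_radius: int = 40,
) -> RoiPair:
    """Place the mesial and distal ROI windows against an anchor landmark.

    For each side the chosen window is the admissible ``width x height``
    rectangle whose inner-edge midpoint lies nearest (Euclidean) to the
    anchor point, searched over integer offsets within ``search_radius`` of
    the ideal abutting position.  Admissible means fully inside the image,
    entirely on its own side of the anchor (a mesial window never crosses
    the implant margin distally, and vice versa) and clearing the exclusion
    mask by at least a 1-px margin.  Ties are broken toward the alveolar
    crest (smaller row), then toward the anchor column.  The function is
    deterministic in its inputs.
    """
    h, w = image.shape
    if exclusion_mask is None:
        exclusion_mask = np.zeros((h, w), dtype=bool)
    exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
    if exclusion_mask.shape != (h, w):
        raise InputError("exclusion mask must match the image dimensions")
    # 1-px clearance: a window may not touch the mask, so test against its dilation
    blocked = ndimage.binary_dilation(exclusion_mask, np.ones((3, 3), dtype=bool))

    pair = RoiPair()
    for side in ("mesial", "distal"):
        ax, ay = anchor.anchor_point(side)
        if not (0 <= ax < w and 0 <= ay < h):
            pair.errors[side] = RoiPlacementError(side, ["anchor outside image"])
            continue
        # ideal position: inner edge abutting the anchor, top row at the anchor row
        ideal_x = int(round(ax + 1)) if side == "distal" else int(round(ax)) - width
        ideal_y = int(round(ay))
        best = None
        for ddy in range(-search_radius, search_radius + 1):
            for ddx in range(-search_radius, search_radius + 1):
                x, y = ideal_x + ddx, ideal_y + ddy
                # stay on the window's own side of the anchor
                if side == "mesial" and x + width > int(np.ceil(ax)):
                    continue
                if side == "distal" and x < int(np.floor(ax)) + 1:
                    continue
                if not _admissible(x, y, width, height, (h, w), blocked):
                    continue
                mid = _inner_edge_midpoint(x, y, width, height, side)
                dist = float(np.hypot(mid[0] - ax, mid[1] - ay))
                key = (dist, y, abs(x - ideal_x))
                if best is None or key < best[0]:
                    best = (key, x, y)
        if best is None:
            pair.errors[side] = RoiPlacementError(
                side,
                [
                    f"no admissible {width}x{height} window within "
                    f"{search_radius} px of the anchor (bounds or exclusion mask)"
                ],
            )
            continue
        _, x, y = best
        setattr(
            pair,
            side,
            RoiSpec(x=x, y=y, width=width, height=height, side=side,
                    anchor=anchor.anchor_name),
        )
    if pair.mesial is None and pair.distal is None:
        raise RoiPlacementError(
            "mesial+distal",
            [str(e) for e in pair.errors.values()],
        )
    return pair


def extract(image: Radiograph, spec: RoiSpec) -> RoiPatch:
    """Pixel-exact copy of the window; no interpolation (images are assumed
    pre-aligned by the registration stage)."""
    if not spec.inside(image.shape):
        raise InputError(f"ROI spec {spec} falls outside image of shape {image.shape}")
    rows, cols = spec.slices()
    return RoiPatch(
        pixels=image.pixels[rows, cols].copy(),
        spec=spec,
        patient_id=image.patient_id,
        timepoint=image.timepoint,
        jaw=image.jaw,
        sex=image.sex,
        age=image.age,
    )
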