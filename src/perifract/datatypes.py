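"""Shared domain containers.

The pipeline passes four kinds of object between stages: a
:class:`Radiograph` (8-bit grayscale image plus visit metadata), a
:class:`RigidTransform` (the alignment of a follow-up onto its baseline),
ROI window definitions and pixel blocks (:class:`RoiSpec`,
:class:`RoiPatch`), and the binary :class:`SkeletonMask` that feeds box
counting.  :class:`FdRecord` is one row of the analysis table consumed by
the statistics stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InputError

TIMEPOINTS = (0, 3, 6, 12)
JAWS = ("maxilla", "mandible")
SEXES = ("female", "male")


@dataclass
class Radiograph:
    """One periapical radiograph: an 8-bit grayscale image plus metadata.

    Pixels are row-major with the origin at the top-left corner and 0-based
    indices, the convention of every array library used downstream.
    """

    pixels: np.ndarray
    dpi: int = 300
    patient_id: str = ""
    timepoint: int = 0
    jaw: str = "mandible"
    sex: str = "female"
    age: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError("radiograph pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InputError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.timepoint not in TIMEPOINTS:
            raise InputError(f"timepoint must be one of {TIMEPOINTS}")
        if self.jaw not in JAWS:
            raise InputError(f"jaw must be one of {JAWS}")
        if self.sex not in SEXES:
            raise InputError(f"sex must be one of {SEXES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Radiograph":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body map: rotate by ``theta`` degrees (counter-clockwise about
    the image center), then translate by ``(dx, dy)`` pixels.

    Forward point map: ``q = R(theta) @ (p - c) + c + (dx, dy)`` where ``p``
    is an ``(x, y)`` point and ``c`` the image center.
    """

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0
    objective: Optional[float] = None

    def matrix(self) -> np.ndarray:
        t = math.radians(self.theta)
        return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])

    def inverse(self) -> "RigidTransform":
        rinv = self.matrix().T
        tx, ty = -rinv @ np.array([self.dx, self.dy])
        return RigidTransform(dx=float(tx), dy=float(ty), theta=-self.theta)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """The transform equivalent to applying ``other`` first, then ``self``."""
        r = self.matrix()
        tx, ty = r @ np.array([other.dx, other.dy]) + np.array([self.dx, self.dy])
        return RigidTransform(dx=float(tx), dy=float(ty), theta=self.theta + other.theta)

    def apply(self, points: np.ndarray, center: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - center) @ self.matrix().T + center + np.array([self.dx, self.dy])
        return out

    def is_identity(self, tol: float = 1e-6) -> bool:
        return abs(self.dx) < tol and abs(self.dy) < tol and abs(self.theta) < tol

    def to_dict(self) -> dict:
        d = {"dx": self.dx, "dy": self.dy, "theta": self.theta}
        if self.objective is not None:
            d["objective"] = self.objective
        return d


@dataclass(frozen=True)
class RoiSpec:
    """A 10x30-pixel analysis window.

    The rectangle is half-open: columns ``[x, x + width)`` and rows
    ``[y, y + height)``, 0-based.  ``side`` records whether the window sits
    mesially or distally of the implant (or control tooth); ``anchor`` records
    the landmark it was placed against.
    """

    x: int
    y: int
    width: int = 10
    height: int = 30
    side: str = "mesial"
    anchor: str = "implant_first_thread"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise InputError("ROI dimensions must be positive")
        if self.side not in ("mesial", "distal"):
            raise InputError("side must be 'mesial' or 'distal'")
        if self.anchor not in ("implant_first_thread", "cej_line"):
            raise InputError("anchor must be 'implant_first_thread' or 'cej_line'")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.height), slice(self.x, self.x + self.width)

    def inside(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return 0 <= self.x and 0 <= self.y and self.x + self.width <= w and self.y + self.height <= h

    def to_dict(self) -> dict:
        return {
            "x": self.x, "y": self.y, "width": self.width, "height": self.height,
            "side": self.side, "anchor": self.anchor,
        }


@dataclass
class RoiPatch:
    """The pixel block extracted through a :class:`RoiSpec`."""

    pixels: np.ndarray
    spec: RoiSpec
    patient_id: str = ""
    timepoint: int = 0
    jaw: str = "mandible"
    sex: str = "female"
    age: float = 0.0

    def __post_init__(self) -> None:
        if self.pixels.shape != (self.spec.height, self.spec.width):
            raise InputError("patch dimensions do not match spec")


#: canonical step names of the preprocessing chain, in order
CHAIN_STEPS = (
    "blur", "subtract", "add128", "threshold", "erode", "dilate", "outline",
    "skeletonize",
)


@dataclass
class SkeletonMask:
    """Binary skeletonized trabecular pattern.

    Foreground pixels proxy trabeculae; background is marrow space.
    ``provenance`` lists the preprocessing steps that produced the mask, in
    canonical order, with the parameters that were active.
    """

    pixels: np.ndarray
    provenance: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass
class FdRecord:
    """Per-visit fractal-dimension record: one row of the analysis table."""

    patient_id: str
    timepoint: int
    fd_mesial: Optional[float]
    fd_distal: Optional[float]
    jaw: str
    sex: str
    age: float
    r2_mesial: Optional[float] = None
    r2_distal: Optional[float] = None

    @property
    def complete(self) -> bool:
        return self.fd_mesial is not None and self.fd_distal is not None

    @property
    def fd_mean(self) -> Optional[float]:
        if not self.complete:
            return None
        return (self.fd_mesial + self.fd_distal) / 2.0

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "timepoint_months": self.timepoint,
            "jaw": self.jaw,
            "sex": self.sex,
            "age": self.age,
            "fd_mesial": self.fd_mesial,
            "fd_distal": self.fd_distal,
            "fd_mean": self.fd_mean,
            "r2_mesial": self.r2_mesial,
            "r2_distal": self.r2_distal,
        }
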