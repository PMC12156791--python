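"""Box-counting fractal dimension of skeletonized trabecular patterns.

A square grid of tile size *s* is laid over the mask from the top-left
corner (edge tiles may be partial; a partial tile counts if it contains at
least one foreground pixel) and the number of occupied tiles N(s) is
recorded for each size in the tile-size ladder.  The fractal dimension is
the negative slope of the ordinary least-squares fit of log N(s) against
log s.  Higher FD means a more complex, more space-filling trabecular
pattern.

The default ladder is (2, 3, 4, 6, 8, 12, 16, 32, 64) pixels.  For tiles
at least as large as the mask the grid degenerates to a single occupied
tile, contributing (log s, 0) points to the fit exactly as the classic
ImageJ box counter does; ``drop_oversized=True`` restricts the ladder to
sizes below the mask's larger dimension instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datatypes import FdRecord, SkeletonMask
from .errors import EmptyMaskError, InputError

__all__ = ["DEFAULT_TILE_SIZES", "BoxCountResult", "box_count", "fd_for_visit"]

DEFAULT_TILE_SIZES: tuple[int, ...] = (2, 3, 4, 6, 8, 12, 16, 32, 64)


@dataclass(frozen=True)
class BoxCountResult:
    """Occupied-tile counts per tile size and the fitted dimension.

    ``grid_origin`` documents the convention: the grid is anchored at the
    mask's top-left corner (0, 0); no origin averaging is performed.
    """

    tile_sizes: tuple[int, ...]
    counts: tuple[int, ...]
    fd: float
    r_squared: float
    grid_origin: tuple[int, int] = (0, 0)

    def loglog_points(self) -> tuple[np.ndarray, np.ndarray]:
        return np.log(np.array(self.tile_sizes, float)), np.log(
            np.array(self.counts, float)
        )

    def plot(self, ax=None):
        """log-log plot of counts vs tile size with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lx, ly = self.loglog_points()
        ax.plot(lx, ly, "o", label="occupied tiles")
        ax.plot(lx, ly.mean() - self.fd * (lx - lx.mean()), "-",
                label=f"fit, FD = {self.fd:.4f}")
        ax.set_xlabel("log tile size (px)")
        ax.set_ylabel("log occupied tiles")
        ax.legend()
        return ax


def _occupied_tiles(mask: np.ndarray, size: int) -> int:
    h, w = mask.shape
    ph = (-h) % size
    pw = (-w) % size
    if ph or pw:
        mask = np.pad(mask, ((0, ph), (0, pw)))
    hh, ww = mask.shape
    blocks = mask.reshape(hh // size, size, ww // size, size)
    return int(blocks.any(axis=(1, 3)).sum())


def box_count(
    mask: SkeletonMask | np.ndarray,
    tile_sizes: Sequence[int] = DEFAULT_TILE_SIZES,
    *,
    drop_oversized: bool = False,
) -> BoxCountResult:
    """Box-count a binary mask and fit the fractal dimension.

    Raises :class:`EmptyMaskError` on an empty mask — the dimension of the
    empty set is undefined and must not silently enter downstream
    statistics as 0.
    """
    px = mask.pixels if isinstance(mask, SkeletonMask) else np.asarray(mask, bool)
    sizes = [int(s) for s in tile_sizes]
    if not sizes or any(s < 1 for s in sizes) or sorted(sizes) != sizes:
        raise InputError("tile sizes must be positive and sorted ascending")
    if px.ndim != 2:
        raise InputError("mask must be 2-D")
    if not px.any():
        raise EmptyMaskError("box-counting dimension is undefined on an empty mask")
    if drop_oversized:
        limit = max(px.shape)
        sizes = [s for s in sizes if s < limit] or sizes[:1]
    counts = [_occupied_tiles(px, s) for s in sizes]

    lx = np.log(np.array(sizes, dtype=float))
    ly = np.log(np.array(counts, dtype=float))
    if len(sizes) == 1 or np.ptp(lx) == 0:
        slope, r2 = 0.0, 1.0
    else:
        slope, intercept = np.polyfit(lx, ly, 1)
        resid = ly - (slope * lx + intercept)
        ss_tot = float(np.sum((ly - ly.mean()) ** 2))
        # a perfectly flat log-count line is a perfect fit, not an undefined one
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return BoxCountResult(
        tile_sizes=tuple(sizes), counts=tuple(counts), fd=float(-slope) + 0.0,
        r_squared=float(r2),
    )


def fd_for_visit(
    mesial: Optional[SkeletonMask],
    distal: Optional[SkeletonMask],
    *,
    patient_id: str,
    timepoint: int,
    jaw: str,
    sex: str,
    age: float,
    tile_sizes: Sequence[int] = DEFAULT_TILE_SIZES,
    drop_oversized: bool = False,
) -> FdRecord:
    """Per-visit record: FD of each side and their exact arithmetic mean.

    A side whose mask is empty (undefined FD) leaves ``None`` in that slot
    and the record flagged incomplete — the valid side is preserved, and
    the mean is not silently computed from one side.
    """
    def _side(m):
        if m is None:
            return None, None
        try:
            r = box_count(m, tile_sizes, drop_oversized=drop_oversized)
        except EmptyMaskError:
            return None, None
        return r.fd, r.r_squared

    fd_m, r2_m = _side(mesial)
    fd_d, r2_d = _side(distal)
    return FdRecord(
        patient_id=patient_id, timepoint=timepoint, fd_mesial=fd_m, fd_distal=fd_d,
        jaw=jaw, sex=sex, age=age, r2_mesial=r2_m, r2_distal=r2_d,
    )
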