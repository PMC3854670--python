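"""Square-window neighborhood extraction around a central pixel.

The joint classification model codes all pixels of a small square window
together, on the assumption that neighboring chromosome pixels share a class.
This module builds the ``n x s`` measurement matrix of a window, handling
image borders and the segmentation-mask boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["WindowSpec", "PatchMatrix", "extract_patch"]


@dataclass(frozen=True)
class WindowSpec:
    """A square window of odd side length.

    ``boundary_policy`` controls pixels falling outside the image or the
    chromosome mask:

    - ``"shrink"`` (default): such pixels are dropped, so the effective patch
      size ``s`` may be smaller than ``side**2``.  Background never enters the
      joint representation.
    - ``"pad-replicate"``: such pixels are replaced by the central pixel's
      feature vector, keeping ``s == side**2``.
    """

    side: int
    boundary_policy: str = "shrink"

    def __post_init__(self) -> None:
        if self.side < 1 or self.side % 2 == 0:
            raise ValueError(f"window side must be odd and >= 1, got {self.side}")
        if self.boundary_policy not in ("shrink", "pad-replicate"):
            raise ValueError(f"unknown boundary_policy {self.boundary_policy!r}")

    @property
    def nominal_s(self) -> int:
        return self.side * self.side

    @classmethod
    def from_size(cls, s: int, boundary_policy: str = "shrink") -> "WindowSpec":
        """Build a spec from the nominal neighborhood size (1, 9, 25, ...)."""
        side = math.isqrt(s)
        if side * side != s or side % 2 == 0:
            raise ValueError(f"neighborhood size s={s} is not an odd square")
        return cls(side=side, boundary_policy=boundary_policy)


@dataclass
class PatchMatrix:
    """The ``n x s`` feature matrix of a neighborhood.

    Column 0 is always the central pixel; the remaining columns follow
    row-major window order.  ``member_coords[j]`` is the image coordinate the
    j-th column was read from (replicated columns carry the center's
    coordinate).
    """

    Y: np.ndarray
    center: tuple[int, int]
    member_coords: list[tuple[int, int]] = field(repr=False)

    @property
    def s(self) -> int:
        return self.Y.shape[1]


def extract_patch(
    channels: np.ndarray,
    mask: np.ndarray,
    center: tuple[int, int],
    window: WindowSpec,
) -> PatchMatrix:
    """Collect the feature vectors of the window centered at ``center``.

    ``channels`` is an ``H x W x n`` stack; ``mask`` a boolean ``H x W`` image
    marking the chromosomal region.  ``center`` must be in-image and in-mask.
    """
    H, W = mask.shape
    r0, c0 = int(center[0]), int(center[1])
    if not (0 <= r0 < H and 0 <= c0 < W):
        raise ValueError(f"center {center} lies outside the {H}x{W} image")
    if not mask[r0, c0]:
        raise ValueError(f"center {center} is not inside the chromosome mask")
    if channels.shape[:2] != mask.shape:
        raise ValueError(
            f"channel stack shape {channels.shape[:2]} does not match mask {mask.shape}"
        )

    half = window.side // 2
    center_vec = channels[r0, c0]
    cols = [center_vec]
    coords = [(r0, c0)]
    replicate = window.boundary_policy == "pad-replicate"
    for dr in range(-half, half + 1):
        for dc in range(-half, half + 1):
            if dr == 0 and dc == 0:
                continue
            r, c = r0 + dr, c0 + dc
            if 0 <= r < H and 0 <= c < W and mask[r, c]:
                cols.append(channels[r, c])
                coords.append((r, c))
            elif replicate:
                cols.append(center_vec)
                coords.append((r0, c0))
    Y = np.stack(cols, axis=1).astype(float)
    return PatchMatrix(Y=Y, center=(r0, c0), member_coords=coords)
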