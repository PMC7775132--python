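"""Maximum intensity projection (MIP).

A nodule occupies only a handful of pixels on any single CT slice, so
2-D appearance alone under-represents its 3-D shape.  Projecting the
maximum gray value through a window of consecutive slices fuses the
local 3-D structure into one 2-D image:

    MIP(x, y) = max( I_first(x, y), ..., I_last(x, y) )

Rays are axial only (along the slice axis), so the projection is a
per-pixel maximum over the chosen slice window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import Image2D, ImageStack

__all__ = ["MIPImage", "compute_mip"]


@dataclass(frozen=True)
class MIPImage:
    """A maximum-intensity projection and the slice window that produced it."""

    image: Image2D
    layer_range: tuple[int, int]

    @property
    def n_layers(self) -> int:
        first, last = self.layer_range
        return last - first + 1


def compute_mip(stack: ImageStack, first: int = 0, last: int | None = None) -> MIPImage:
    """Project the per-pixel maximum over slices ``first..last`` (inclusive).

    Parameters
    ----------
    stack
        The slice stack.
    first, last
        Inclusive slice window; ``last=None`` means the final slice.

    Returns
    -------
    MIPImage
        2-D projection with the same in-plane dimensions as the stack.
    """
    if last is None:
        last = stack.n_slices - 1
    if not (0 <= first <= last < stack.n_slices):
        raise ValueError(
            f"layer range [{first}, {last}] out of bounds for {stack.n_slices} slices"
        )
    volume = stack.as_array()[first : last + 1]
    return MIPImage(Image2D(volume.max(axis=0)), (first, last))
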