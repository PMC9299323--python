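"""Organ-mask erosion and SCF-percentile region partitioning.

The eroded organ mask keeps the evaluation away from the segmentation
boundary; inside it, the SCF distribution is split at two percentiles:
pixels at or below the low cut (default 10th) form the homogeneous region
R_H used for noise measurement, pixels at or above the high cut (default
70th) form the structure-edge region R_S used for sharpness and
structure-alteration measurement.  Pixels in between belong to neither.
Percentiles are computed per slice over the eroded mask only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .image_io import OrganMask
from .scf import SCFMap

__all__ = [
    "SliceExcluded",
    "RegionPartition",
    "erode_mask",
    "partition_regions",
]

#: Minimum number of defined SCF pixels needed to partition a slice.
MIN_DEFINED_PIXELS = 100


class SliceExcluded(RuntimeError):
    """A slice cannot be evaluated; the message is the exclusion reason."""


@dataclass
class RegionPartition:
    """Disjoint homogeneous (r_h) and structure-edge (r_s) pixel sets.

    ``p_low``/``p_high`` are the SCF cut values actually used.  When the
    two cuts coincide (constant SCF), every pixel goes to r_h, r_s is
    empty and ``degenerate`` is set: such a slice has no measurable
    structure.
    """

    r_h: np.ndarray
    r_s: np.ndarray
    eroded_mask: np.ndarray
    p_low: float
    p_high: float
    degenerate: bool = False

    @property
    def n_rh(self) -> int:
        return int(self.r_h.sum())

    @property
    def n_rs(self) -> int:
        return int(self.r_s.sum())


def erode_mask(mask: OrganMask | np.ndarray, element_px: int = 7, shape: str = "square") -> np.ndarray:
    """Binary erosion with a square (side) or disk (diameter) element.

    Raises :class:`SliceExcluded` ("mask vanished under erosion") when
    nothing survives.
    """
    m = (mask.mask if isinstance(mask, OrganMask) else np.asarray(mask)) != 0
    if not m.any():
        raise SliceExcluded("mask vanished under erosion")
    if element_px < 1:
        raise ValueError("element_px must be >= 1")
    if element_px == 1:
        return m.copy()
    if shape == "square":
        structure = np.ones((element_px, element_px), dtype=bool)
    elif shape == "disk":
        structure = disk(element_px // 2).astype(bool)
    else:
        raise ValueError(f"unknown erosion element shape: {shape!r}")
    eroded = ndimage.binary_erosion(m, structure=structure)
    if not eroded.any():
        raise SliceExcluded("mask vanished under erosion")
    return eroded


def partition_regions(
    scf: SCFMap,
    eroded: np.ndarray | OrganMask,
    low_pct: float = 10.0,
    high_pct: float = 70.0,
) -> RegionPartition:
    """Threshold the SCF map at its low/high percentiles within the eroded mask.

    Percentiles use the linear-interpolation definition; ties at the cut
    value are included in the region (<= low cut, >= high cut), so region
    sizes can exceed the nominal fractions.
    """
    if not low_pct < high_pct:
        raise ValueError("low_pct must be < high_pct")
    em = (eroded.mask if isinstance(eroded, OrganMask) else np.asarray(eroded)) != 0
    defined = em & scf.defined
    n = int(defined.sum())
    if n < MIN_DEFINED_PIXELS:
        raise SliceExcluded(f"too few defined SCF pixels ({n} < {MIN_DEFINED_PIXELS})")
    vals = scf.values[defined]
    p_low = float(np.percentile(vals, low_pct))
    p_high = float(np.percentile(vals, high_pct))
    if p_low == p_high:
        # constant SCF: no measurable structure
        return RegionPartition(
            r_h=defined.copy(), r_s=np.zeros_like(defined),
            eroded_mask=em, p_low=p_low, p_high=p_high, degenerate=True,
        )
    r_h = defined & (scf.values <= p_low)
    r_s = defined & (scf.values >= p_high)
    return RegionPartition(r_h=r_h, r_s=r_s, eroded_mask=em, p_low=p_low, p_high=p_high)
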