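"""The three automated image-quality metrics.

* Noise level: mean sample SD of HU values over five randomly placed
  square ROIs inside the homogeneous region R_H.
* Structure sharpness index (SSI): mean SCF over the structure-edge
  region R_S, optionally mapped to a physical edge slope (HU/mm) by a
  linear calibration.
* Structure alteration index (SAI): for a pair of co-registered
  reconstructions, the SD ratio of the difference image between R_S and
  R_H.  Uniform noise removal gives SAI ~ 1; structure smearing
  concentrates the difference at edges and drives SAI above 1.

Sample standard deviations use the N-1 denominator throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .image_io import CTImage
from .partition import RegionPartition
from .scf import SCFMap

__all__ = [
    "NoiseResult",
    "SSIResult",
    "SAIResult",
    "noise_level",
    "structure_sharpness",
    "fit_ssi_calibration",
    "structure_alteration",
]

log = logging.getLogger(__name__)

#: Default SSI-to-edge-slope calibration (HU/mm per unit SCF and offset),
#: fitted on a single phantom/scanner; recalibrate via fit_ssi_calibration
#: for other acquisition conditions.
DEFAULT_SSI_COEF_A = 6.1398
DEFAULT_SSI_COEF_B = 4.2813


@dataclass
class NoiseResult:
    noise_hu: float
    roi_centers: list[tuple[int, int]]
    roi_size_px: int
    seed: int
    roi_sds: list[float]


@dataclass
class SSIResult:
    ssi_raw: float
    ssi_calibrated: float
    coef_a: float
    coef_b: float
    valid: bool = True


@dataclass
class SAIResult:
    sai: float
    sigma_rs: float
    sigma_rh: float
    valid: bool = True


def _eligible_centers(r_h: np.ndarray, size: int) -> np.ndarray:
    """Centers whose full size x size ROI lies inside r_h (and the image)."""
    structure = np.ones((size, size), dtype=bool)
    return np.argwhere(ndimage.binary_erosion(r_h, structure=structure))


def noise_level(
    image: CTImage,
    partition: RegionPartition,
    roi_size_px: int = 21,
    n_rois: int = 5,
    seed: int = 0,
) -> NoiseResult:
    """Mean ROI standard deviation inside the homogeneous region.

    ``n_rois`` square ROIs (side ``roi_size_px``) are drawn without
    replacement from the centers whose whole ROI fits inside R_H, using a
    seeded RNG; the result is reproducible given (image, partition,
    roi_size, seed).  If R_H cannot host enough ROIs the size shrinks by 2
    (odd sizes) down to 5 before failing.
    """
    if roi_size_px < 5 or roi_size_px % 2 == 0:
        raise ValueError("roi_size_px must be odd and >= 5")
    size = roi_size_px
    centers = None
    while size >= 5:
        cand = _eligible_centers(partition.r_h, size)
        if len(cand) >= n_rois:
            centers = cand
            break
        size -= 2
    if centers is None:
        raise RuntimeError("R_H too fragmented to host noise ROIs")
    if size != roi_size_px:
        log.warning("noise ROI shrunk from %d to %d px", roi_size_px, size)

    rng = np.random.default_rng(seed)
    pick = rng.choice(len(centers), size=n_rois, replace=False)
    half = size // 2
    sds = []
    chosen = []
    occupancy = np.zeros(image.pixels.shape, dtype=np.int32)
    for r, c in centers[np.sort(pick)]:
        roi = image.pixels[r - half : r + half + 1, c - half : c + half + 1]
        sds.append(float(np.std(roi, ddof=1)))
        chosen.append((int(r), int(c)))
        occupancy[r - half : r + half + 1, c - half : c + half + 1] += 1
    if (occupancy > 1).any():
        log.info("noise ROIs overlap on %d pixels", int((occupancy > 1).sum()))
    return NoiseResult(
        noise_hu=float(np.mean(sds)),
        roi_centers=chosen, roi_size_px=size, seed=seed, roi_sds=sds,
    )


def structure_sharpness(
    scf: SCFMap,
    partition: RegionPartition,
    coef_a: float = DEFAULT_SSI_COEF_A,
    coef_b: float = DEFAULT_SSI_COEF_B,
) -> SSIResult:
    """Mean SCF over R_S plus its linear mapping to an edge slope."""
    if partition.degenerate or partition.n_rs == 0:
        return SSIResult(ssi_raw=float("nan"), ssi_calibrated=float("nan"),
                         coef_a=coef_a, coef_b=coef_b, valid=False)
    raw = float(np.mean(scf.values[partition.r_s]))
    return SSIResult(ssi_raw=raw, ssi_calibrated=coef_a * raw + coef_b,
                     coef_a=coef_a, coef_b=coef_b)


def fit_ssi_calibration(pairs: list[tuple[float, float]]) -> tuple[float, float, float]:
    """OLS fit of reference edge slope on raw SSI.

    Returns (slope, intercept, Pearson r).  Needs >= 3 pairs with a
    nonconstant predictor.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (ssi_raw, slope) pairs")
    x = np.asarray([p[0] for p in pairs], dtype=np.float64)
    y = np.asarray([p[1] for p in pairs], dtype=np.float64)
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: cannot fit calibration")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def structure_alteration(
    reference: CTImage,
    target: CTImage,
    partition: RegionPartition,
) -> SAIResult:
    """SD ratio of the reference-minus-target image between R_S and R_H.

    The partition must come from the reference reconstruction; both images
    must share the grid.  A pair with zero difference SD in R_H (e.g.
    identical images) is flagged invalid ("no-op denoiser").
    """
    if reference.pixels.shape != target.pixels.shape:
        raise ValueError("reference and target shapes differ")
    di = reference.pixels - target.pixels
    sigma_rs = float(np.std(di[partition.r_s], ddof=1)) if partition.n_rs > 1 else 0.0
    sigma_rh = float(np.std(di[partition.r_h], ddof=1)) if partition.n_rh > 1 else 0.0
    if sigma_rh == 0.0:
        return SAIResult(sai=float("nan"), sigma_rs=sigma_rs, sigma_rh=sigma_rh, valid=False)
    return SAIResult(sai=sigma_rs / sigma_rh, sigma_rs=sigma_rs, sigma_rh=sigma_rh)
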