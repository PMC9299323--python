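"""Structure coherence feature (SCF).

The SCF scores, per pixel, how likely its neighbourhood is to contain a
coherent anatomical structure (a vessel wall, an organ boundary) rather
than homogeneous parenchyma or unstructured noise.  For a square window W
centred on the pixel and intersected with the organ mask,

    SCF = sum_{(i,j) in W} I_E(i,j) / (H_G + H_T),

where the edginess I_E = w1*|grad I| + w2*|lambda1| combines the gradient
magnitude with the first eigenvalue of the 2x2 structure tensor

    T = [Ix^2, Ix*Iy; Ix*Iy, Iy^2],

and H_G, H_T are Shannon entropies of the orientation histograms of the
gradient vectors (on [-pi, pi)) and of the tensor's first eigenvectors
(on [0, pi); an eigenvector's sign is arbitrary).  A straight edge has a
large, orientation-coherent gradient (large numerator, small entropies);
pure noise has random orientations (entropies near ln n_bins), so edges
score high and homogeneous regions score low.

The whole map is computed with separable box filters (per-bin orientation
counts and edginess sums), so cost is O(n_bins) filter passes per slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy import ndimage

from .image_io import CTImage, OrganMask

__all__ = [
    "SCFParams",
    "GradientField",
    "StructureTensorField",
    "SCFMap",
    "compute_gradient",
    "compute_structure_tensor",
    "edginess",
    "directional_entropy",
    "compute_scf_map",
]


@dataclass
class SCFParams:
    """Tunables of the SCF computation.

    omega1, omega2
        Weights of gradient magnitude and first tensor eigenvalue in the
        edginess.  Note |lambda1| of the pointwise tensor equals |grad I|^2,
        so the two terms scale differently with image contrast.
    window_px
        Odd side of the square evaluation window (default 9 px, roughly
        6 mm at typical abdominal CT spacing).
    n_angle_bins
        Equal-width orientation histogram bins for both entropies.
    entropy_floor
        Small constant added to (H_G + H_T) so perfectly coherent windows
        (both entropies zero) do not divide by zero.
    tensor_smooth_sigma_px
        Gaussian smoothing of the tensor components before eigenanalysis;
        0 means pointwise products, for which the tensor is rank one and
        lambda1 = |grad I|^2 identically.
    """

    omega1: float = 1.0
    omega2: float = 1.0
    window_px: int = 9
    n_angle_bins: int = 8
    entropy_floor: float = 1e-6
    tensor_smooth_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if self.omega1 < 0 or self.omega2 < 0 or self.omega1 + self.omega2 <= 0:
            raise ValueError("need nonnegative weights with omega1 + omega2 > 0")
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise ValueError("window_px must be odd and >= 3")
        if self.n_angle_bins < 4:
            raise ValueError("n_angle_bins must be >= 4")
        if self.entropy_floor <= 0:
            raise ValueError("entropy_floor must be positive")
        if self.tensor_smooth_sigma_px < 0:
            raise ValueError("tensor_smooth_sigma_px must be >= 0")

    def to_flat_dict(self) -> dict:
        return {f"scf.{k}": v for k, v in asdict(self).items()}


@dataclass
class GradientField:
    """Central-difference image gradient in HU/mm."""

    gx: np.ndarray  # d/d(col)
    gy: np.ndarray  # d/d(row)
    magnitude: np.ndarray
    angle: np.ndarray  # atan2(gy, gx), in [-pi, pi)


@dataclass
class StructureTensorField:
    t11: np.ndarray
    t12: np.ndarray
    t22: np.ndarray
    lambda1: np.ndarray
    vt_angle: np.ndarray  # orientation of the first eigenvector, in [0, pi)


@dataclass
class SCFMap:
    """Per-pixel SCF values; NaN outside the evaluated mask."""

    values: np.ndarray
    window_px: int
    params: SCFParams = field(repr=False)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def compute_gradient(image: CTImage) -> GradientField:
    """Central differences with edge replication, scaled by spacing per axis."""
    p = np.pad(image.pixels, 1, mode="edge")
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / (2.0 * image.spacing_row_mm)
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / (2.0 * image.spacing_col_mm)
    magnitude = np.hypot(gx, gy)
    angle = np.arctan2(gy, gx)
    angle[angle == np.pi] = -np.pi  # half-open [-pi, pi)
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, angle=angle)


def compute_structure_tensor(grad: GradientField, params: SCFParams | None = None) -> StructureTensorField:
    """Structure tensor, first eigenvalue and eigenvector orientation.

    Components are optionally Gaussian-smoothed (sigma in pixels).  The
    eigenpair comes from the 2x2 closed form:

        lambda1 = ((t11 + t22) + D) / 2,   D = sqrt((t11 - t22)^2 + 4 t12^2)
        v1 ∝ (2 t12, t22 - t11 + D)

    which satisfies T v1 = lambda1 v1.  When t12 = 0 the formula degenerates
    and the axis-aligned eigenvector is taken directly (angle 0 if
    t11 >= t22, else pi/2).
    """
    params = params or SCFParams()
    t11 = grad.gx * grad.gx
    t12 = grad.gx * grad.gy
    t22 = grad.gy * grad.gy
    s = params.tensor_smooth_sigma_px
    if s > 0:
        t11 = ndimage.gaussian_filter(t11, s)
        t12 = ndimage.gaussian_filter(t12, s)
        t22 = ndimage.gaussian_filter(t22, s)
    disc = np.hypot(t11 - t22, 2.0 * t12)
    lambda1 = 0.5 * ((t11 + t22) + disc)

    vx = 2.0 * t12
    vy = (t22 - t11) + disc
    vt_angle = np.mod(np.arctan2(vy, vx), np.pi)
    vt_angle[vt_angle >= np.pi] = 0.0
    # t12 == 0 and t22 <= t11 gives the zero vector: the eigenvector is axis-aligned
    degenerate = (vx == 0) & (vy == 0)
    vt_angle[degenerate] = np.where(t11[degenerate] >= t22[degenerate], 0.0, np.pi / 2)
    return StructureTensorField(t11=t11, t12=t12, t22=t22, lambda1=lambda1, vt_angle=vt_angle)


def edginess(grad: GradientField, tensor: StructureTensorField, params: SCFParams) -> np.ndarray:
    """I_E = omega1*|grad I| + omega2*|lambda1|, pointwise and nonnegative."""
    return params.omega1 * grad.magnitude + params.omega2 * np.abs(tensor.lambda1)


def directional_entropy(
    angles: np.ndarray,
    valid: np.ndarray | None = None,
    n_bins: int = 8,
    domain: Literal["full_circle", "half_circle"] = "full_circle",
) -> float:
    """Shannon entropy (natural log) of an orientation histogram.

    ``domain`` selects the angular support: [-pi, pi) for gradient
    directions, [0, pi) for eigenvector orientations.  Pixels flagged
    invalid (e.g. zero gradient magnitude, angle undefined) are excluded;
    an empty-after-exclusion window returns 0 by convention.
    """
    a = np.asarray(angles, dtype=np.float64).ravel()
    if valid is not None:
        a = a[np.asarray(valid, dtype=bool).ravel()]
    if a.size == 0:
        return 0.0
    lo, hi = (-np.pi, np.pi) if domain == "full_circle" else (0.0, np.pi)
    idx = np.floor((a - lo) / (hi - lo) * n_bins).astype(np.intp)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Sum of x over the w x w window at each pixel, zeros outside the image."""
    return ndimage.uniform_filter(x, size=w, mode="constant", cval=0.0) * float(w * w)


def _window_entropies(bin_idx: np.ndarray, valid: np.ndarray, n_bins: int, w: int) -> np.ndarray:
    """Per-pixel entropy of the windowed orientation histogram.

    Box-filter counts are rounded back to integers so the result is exactly
    the histogram entropy (no filter round-off leaking into probabilities).
    """
    counts = np.empty((n_bins,) + bin_idx.shape, dtype=np.float64)
    for b in range(n_bins):
        counts[b] = np.rint(_window_sums(((bin_idx == b) & valid).astype(np.float64), w))
    total = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / total
        terms = np.where(counts > 0, -p * np.log(p), 0.0)
    h = terms.sum(axis=0)
    h[total == 0] = 0.0
    return h


def compute_scf_map(image: CTImage, mask: OrganMask | np.ndarray, params: SCFParams | None = None) -> SCFMap:
    """Compute the SCF at every pixel of the evaluated mask.

    The window centred at each mask pixel is intersected with the mask (and
    the image support); pixels with zero gradient magnitude contribute no
    orientation sample.  Values outside the mask are NaN.
    """
    params = params or SCFParams()
    m = (mask.mask if isinstance(mask, OrganMask) else np.asarray(mask)) != 0
    if m.shape != image.pixels.shape:
        raise ValueError("mask shape does not match image")
    w = params.window_px

    grad = compute_gradient(image)
    tensor = compute_structure_tensor(grad, params)
    ie = edginess(grad, tensor, params)

    sum_ie = np.maximum(_window_sums(ie * m, w), 0.0)

    valid = m & (grad.magnitude > 0)
    nb = params.n_angle_bins
    g_idx = np.clip(np.floor((grad.angle + np.pi) / (2 * np.pi) * nb).astype(np.intp), 0, nb - 1)
    t_idx = np.clip(np.floor(tensor.vt_angle / np.pi * nb).astype(np.intp), 0, nb - 1)
    h_g = _window_entropies(g_idx, valid, nb, w)
    h_t = _window_entropies(t_idx, valid, nb, w)

    values = sum_ie / (h_g + h_t + params.entropy_floor)
    values[~m] = np.nan
    return SCFMap(values=values, window_px=w, params=params)
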