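"""Edge-slope reference measurement and agreement statistics.

This module implements the manual-reference sharpness measure the SSI is
calibrated against: intensity profiles are sampled on perpendiculars
spaced along a drawn tissue-vessel edge polyline, each profile is clipped
to its 10-90% intensity rise, and the sharpness of profile l is the OLS
slope

    xi_l = cov[s_l, I_l] / var[s_l]        (HU/mm)

of intensity on physical distance over the clipped span; the mean of the
xi_l is the reference sharpness of the edge.  Pearson correlation and
Bland-Altman limits of agreement compare two paired measurement series.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .image_io import CTImage

__all__ = [
    "EdgeLine",
    "Profile",
    "EdgeProfileSet",
    "AgreementStats",
    "sample_perpendicular_profiles",
    "clip_profile_10_90",
    "profile_slope",
    "measure_edge_slopes",
    "agreement_stats",
]

log = logging.getLogger(__name__)


@dataclass
class EdgeLine:
    """Ordered polyline of (row, col) vertices along a tissue boundary."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("EdgeLine needs an (N, 2) array with N >= 2")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        self.vertices = v

    @classmethod
    def from_csv(cls, path: str | Path) -> "EdgeLine":
        return cls(np.loadtxt(path, delimiter=",", ndmin=2))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        np.savetxt(path, self.vertices, delimiter=",", fmt="%.6f")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "EdgeLine":
        return cls(np.asarray(json.loads(Path(path).read_text())["vertices"]))


@dataclass
class Profile:
    """One perpendicular profile: distances s (mm) and intensities (HU)."""

    s: np.ndarray
    intensity: np.ndarray


@dataclass
class EdgeProfileSet:
    profiles: list[Profile]
    slopes: list[float] = field(default_factory=list)

    @property
    def mean_slope(self) -> float:
        return float(np.mean(self.slopes)) if self.slopes else float("nan")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def sample_perpendicular_profiles(
    image: CTImage,
    line: EdgeLine,
    spacing_along_mm: float = 1.0,
    half_length_mm: float = 5.0,
    step_mm: float | None = None,
) -> EdgeProfileSet:
    """Sample bilinear-interpolated profiles on perpendiculars to the polyline.

    Profile origins sit at equal arc length along the line (in physical
    mm); each profile runs from -half_length to +half_length along the
    local unit normal in steps of ``step_mm`` (default: a quarter of the
    smaller pixel spacing, so sharp sub-2-px edges still yield enough
    samples inside the 10-90% clip).  The normal at an interior vertex
    averages the adjacent
    segment normals.  Each profile is oriented so it rises (mean intensity
    on the + side >= - side); profiles leaving the image are dropped with
    a warning.
    """
    sp = np.array([image.spacing_row_mm, image.spacing_col_mm])
    step = float(step_mm) if step_mm is not None else float(sp.min()) / 4.0
    verts_mm = line.vertices * sp  # (row_mm, col_mm)
    seg = np.diff(verts_mm, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    eps = 1e-9 * max(total, 1.0)
    origins_s = np.arange(0.0, total + eps, spacing_along_mm)

    offsets = np.arange(-half_length_mm, half_length_mm + 1e-9, step)
    nrows, ncols = image.pixels.shape
    profiles: list[Profile] = []
    n_dropped = 0
    for s0 in origins_s:
        i = min(int(np.searchsorted(cum, s0, side="right")) - 1, len(seg) - 1)
        i = max(i, 0)
        frac = (s0 - cum[i]) / seg_len[i]
        origin = verts_mm[i] + frac * seg[i]
        # tangent: segment direction, averaged at interior vertices
        at_vertex = None
        for j in range(1, len(verts_mm) - 1):
            if abs(s0 - cum[j]) < 1e-9 * max(total, 1.0):
                at_vertex = j
                break
        if at_vertex is not None:
            t = _unit(_unit(seg[at_vertex - 1]) + _unit(seg[at_vertex]))
        else:
            t = _unit(seg[i])
        normal = np.array([-t[1], t[0]])

        pts_mm = origin[None, :] + offsets[:, None] * normal[None, :]
        rows = pts_mm[:, 0] / sp[0]
        cols = pts_mm[:, 1] / sp[1]
        if rows.min() < 0 or cols.min() < 0 or rows.max() > nrows - 1 or cols.max() > ncols - 1:
            n_dropped += 1
            continue
        vals = ndimage.map_coordinates(image.pixels, [rows, cols], order=1)
        s = offsets.copy()
        if vals[s > 0].mean() < vals[s < 0].mean():
            s, vals = -s[::-1], vals[::-1]
        profiles.append(Profile(s=s, intensity=vals))
    if n_dropped:
        log.warning("%d profiles exited the image and were dropped", n_dropped)
    return EdgeProfileSet(profiles=profiles)


def clip_profile_10_90(profile: Profile) -> Profile | None:
    """Clip a rising profile to its 10-90% intensity rise.

    The baseline is the mean of the first quartile of samples (the leading
    plateau); thresholds sit at baseline + 0.10/0.90 of (max - baseline).
    The clip keeps samples from the first position at or above the 10%
    threshold through the first position at or above the 90% threshold.
    Returns None (profile dropped) for flat profiles or clips with fewer
    than 4 samples.
    """
    s, inten = profile.s, profile.intensity
    n = len(s)
    q = max(1, n // 4)
    baseline = float(inten[:q].mean())
    peak = float(inten.max())
    if peak <= baseline:
        return None
    thr10 = baseline + 0.10 * (peak - baseline)
    thr90 = baseline + 0.90 * (peak - baseline)
    above10 = np.nonzero(inten >= thr10)[0]
    above90 = np.nonzero(inten >= thr90)[0]
    if len(above10) == 0 or len(above90) == 0:
        return None
    i10, i90 = int(above10[0]), int(above90[0])
    if i90 - i10 + 1 < 4:
        return None
    return Profile(s=s[i10 : i90 + 1], intensity=inten[i10 : i90 + 1])


def profile_slope(profile: Profile) -> float:
    """OLS slope of intensity on distance (cov[s, I] / var[s]), HU/mm."""
    s, inten = profile.s, profile.intensity
    if len(s) < 4:
        raise ValueError("need at least 4 samples for a slope")
    ds = s - s.mean()
    var = float((ds * ds).sum())
    if var == 0:
        raise ValueError("constant sample positions: slope undefined")
    return float((ds * (inten - inten.mean())).sum() / var)


def measure_edge_slopes(
    image: CTImage,
    line: EdgeLine,
    spacing_along_mm: float = 1.0,
    half_length_mm: float = 5.0,
    step_mm: float | None = None,
) -> EdgeProfileSet:
    """Sample, clip and fit every profile; slopes of dropped profiles are omitted."""
    pset = sample_perpendicular_profiles(image, line, spacing_along_mm, half_length_mm, step_mm)
    kept: list[Profile] = []
    slopes: list[float] = []
    for p in pset.profiles:
        clipped = clip_profile_10_90(p)
        if clipped is None:
            continue
        kept.append(clipped)
        slopes.append(profile_slope(clipped))
    if len(slopes) < len(pset.profiles):
        log.info("dropped %d/%d profiles in clipping", len(pset.profiles) - len(slopes), len(pset.profiles))
    return EdgeProfileSet(profiles=kept, slopes=slopes)


@dataclass
class AgreementStats:
    pearson_r: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    valid: bool = True


def agreement_stats(x, y) -> AgreementStats:
    """Pearson correlation and Bland-Altman statistics for paired series.

    Differences are x - y; limits of agreement are mean +/- 1.96 SD
    (sample SD).  Zero variance in either series leaves r undefined
    (NaN, flagged).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series with at least 3 points")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(np.std(d, ddof=1))
    loa_low, loa_high = mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AgreementStats(float("nan"), mean_diff, sd_diff, loa_low, loa_high, valid=False)
    r = float(stats.pearsonr(x, y).statistic)
    return AgreementStats(r, mean_diff, sd_diff, loa_low, loa_high)
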