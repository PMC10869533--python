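"""Quantitative texture and shape features over a masked ROI.

Families (method codes used in feature names):

* ``FOD``  — first-order / histogram statistics of the raw intensities;
* ``COM``  — gray-level co-occurrence matrix (GLCM);
* ``RLM``  — gray-level run-length matrix (GLRLM);
* ``DIF``  — gray-level difference matrix (histogram of |dG| at a distance);
* ``SZM``  — gray-level size-zone matrix (GLSZM, 8-connected zones);
* ``NTM``  — neighborhood gray-tone difference matrix (Amadasun & King);
* ``NDM``  — neighborhood gray-level dependency matrix;
* ``SHAPE`` — mask geometry.

All matrix families work on a :class:`QuantizedROI`: intensities inside
the mask binned into ``1..Ng`` equal-width levels between the in-mask min
and max (a constant ROI maps to all ones).  Out-of-mask pixels never enter
any matrix or statistic.

Degenerate-case rule: on a constant ROI, features whose definition reduces
to 0/0 return their limit where one exists (GLCM correlation -> 1), else
0.  Each such case is noted at its formula.

Feature names follow ``<MethodPrefix><Family>_<Feature>[_component=k]
[_distance=d]``: ``FOD_Mean`` on the raw ROI, ``CMS-WSZM_ZoneEntropy_component=4``
on wavelet subband 4, ``CMS-CCOM_Correlation_component=14_distance=3`` on
contourlet subband 14, ``LoG-FOD_Mean_sigma=1`` after LoG filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix
from skimage.measure import label as sk_label, regionprops

from .subbands import contourlet_decompose, log_filter, wavelet_decompose

logger = logging.getLogger("galambda")

__all__ = [
    "QuantizedROI",
    "FeatureVectorRecord",
    "ExtractionConfig",
    "quantize",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_difference_features",
    "ngtdm_features",
    "dependency_features",
    "shape_features",
    "extract_all",
]

_EPS = 1e-12
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class QuantizedROI:
    gray_levels: np.ndarray  # int matrix; in-mask values in 1..Ng, 0 outside
    Ng: int
    mask: np.ndarray
    provenance: tuple[str, str, int] = ("", "raw", 0)


@dataclass(frozen=True)
class FeatureVectorRecord:
    feature_name: str
    value: float


def quantize(image: np.ndarray, mask: np.ndarray, Ng: int = 32) -> QuantizedROI:
    """Equal-width binning of in-mask intensities into ``1..Ng``.

    ``g = floor((v - min) / (max - min) * Ng) + 1`` clipped to Ng; a
    constant ROI maps to all ones."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    if Ng < 2:
        raise ValueError("Ng must be >= 2")
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(image.shape, dtype=int)
    if hi > lo:
        g = np.floor((image - lo) / (hi - lo) * Ng).astype(int) + 1
        levels[mask] = np.clip(g[mask], 1, Ng)
    else:
        levels[mask] = 1
    return QuantizedROI(gray_levels=levels, Ng=Ng, mask=mask)


# --------------------------------------------------------------------------
# First order


def first_order_features(
    roi: QuantizedROI, raw_values: np.ndarray | None = None
) -> list[FeatureVectorRecord]:
    """Histogram statistics of the raw in-mask intensities.

    Percentiles use linear interpolation between closest ranks; kurtosis
    is the non-excess (Pearson) moment ratio, 3 for a normal sample.
    Entropy is over the quantized-level histogram (base-2).  On a constant
    ROI: variance, skewness and entropy are 0 and kurtosis is 0 (0/0 form).
    """
    if raw_values is None:
        raw_values = roi.gray_levels[roi.mask].astype(float)
    v = np.asarray(raw_values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 in-mask pixels")
    mean = float(v.mean())
    var = float(v.var())
    sd = np.sqrt(var)
    if sd > _EPS:
        skew = float(np.mean((v - mean) ** 3) / sd**3)
        kurt = float(np.mean((v - mean) ** 4) / sd**4)
    else:
        skew, kurt = 0.0, 0.0  # 0/0 on constant input
    counts = np.bincount(roi.gray_levels[roi.mask], minlength=roi.Ng + 1)[1:]
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    feats = {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Entropy": entropy,
        "10Percentile": float(np.percentile(v, 10)),
        "90Percentile": float(np.percentile(v, 90)),
        "Energy": float(np.sum(v**2)),
        "Minimum": float(v.min()),
        "Maximum": float(v.max()),
        "Range": float(np.ptp(v)),
    }
    return [FeatureVectorRecord(f"FOD_{k}", x) for k, x in feats.items()]


# --------------------------------------------------------------------------
# GLCM


def _glcm_matrix(
    roi: QuantizedROI, distance: int, angles: tuple[int, ...]
) -> np.ndarray:
    """Symmetric normalized GLCM averaged over angles.

    Out-of-mask pixels carry level 0; pairs touching them are excluded by
    discarding matrix row/column 0."""
    rad = {0: 0.0, 45: np.pi / 4, 90: np.pi / 2, 135: 3 * np.pi / 4}
    P = graycomatrix(
        roi.gray_levels.astype(np.uint8) if roi.Ng < 256 else roi.gray_levels,
        distances=[distance],
        angles=[rad[a] for a in angles],
        levels=roi.Ng + 1,
        symmetric=True,
    )[1:, 1:, 0, :].astype(float)
    mats = []
    for k in range(P.shape[2]):
        s = P[:, :, k].sum()
        if s > 0:
            mats.append(P[:, :, k] / s)
    if not mats:
        raise ValueError("zero valid pixel pairs at the requested distance")
    return np.mean(mats, axis=0)


def glcm_features(
    roi: QuantizedROI,
    distance: int = 1,
    angles: tuple[int, ...] = (0, 45, 90, 135),
) -> list[FeatureVectorRecord]:
    """Contrast, correlation, energy, entropy, homogeneity of the GLCM.

    Correlation = sum_ij (i-mu_i)(j-mu_j) p_ij / (s_i s_j); on a constant
    ROI both marginal deviations vanish and the limit 1 is returned."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    p = _glcm_matrix(roi, distance, angles)
    i = np.arange(1, roi.Ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum(p * (ii - jj) ** 2))
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    s_i = np.sqrt(np.sum((ii - mu_i) ** 2 * p))
    s_j = np.sqrt(np.sum((jj - mu_j) ** 2 * p))
    if s_i > _EPS and s_j > _EPS:
        corr = float(np.sum((ii - mu_i) * (jj - mu_j) * p) / (s_i * s_j))
    else:
        corr = 1.0  # zero-variance marginals: defined limit
    energy = float(np.sum(p**2))
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    homo = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    feats = {
        "Contrast": contrast,
        "Correlation": corr,
        "Energy": energy,
        "Entropy": entropy,
        "Homogeneity": homo,
    }
    return [
        FeatureVectorRecord(f"COM_{k}_distance={distance}", x)
        for k, x in feats.items()
    ]


# --------------------------------------------------------------------------
# GLRLM


def _runs_along(
    levels: np.ndarray, mask: np.ndarray, direction: tuple[int, int]
) -> list[tuple[int, int]]:
    """(gray level, run length) of maximal constant runs along one
    direction; runs break at the mask boundary."""
    h, w = levels.shape
    dr, dc = direction
    runs: list[tuple[int, int]] = []
    starts = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if not (0 <= r - dr < h and 0 <= c - dc < w)
    ]
    for r0, c0 in starts:
        r, c = r0, c0
        cur_level, cur_len = None, 0
        while 0 <= r < h and 0 <= c < w:
            if mask[r, c]:
                g = levels[r, c]
                if g == cur_level:
                    cur_len += 1
                else:
                    if cur_level is not None:
                        runs.append((cur_level, cur_len))
                    cur_level, cur_len = g, 1
            else:
                if cur_level is not None:
                    runs.append((cur_level, cur_len))
                cur_level, cur_len = None, 0
            r += dr
            c += dc
        if cur_level is not None:
            runs.append((cur_level, cur_len))
    return runs


def _glrlm_single(roi: QuantizedROI, angle: int) -> np.ndarray:
    runs = _runs_along(roi.gray_levels, roi.mask, _ANGLE_OFFSETS[angle])
    max_len = roi.mask.sum()
    R = np.zeros((roi.Ng, max_len))
    for g, length in runs:
        R[g - 1, length - 1] += 1
    return R


def _glrlm_feature_dict(R: np.ndarray) -> dict[str, float]:
    Nr = R.sum()
    if Nr == 0:
        return {}
    i = np.arange(1, R.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, R.shape[1] + 1, dtype=float)[None, :]
    r_g = R.sum(axis=1)  # per gray level
    r_l = R.sum(axis=0)  # per run length
    return {
        "ShortRunEmphasis": float(np.sum(R / l**2) / Nr),
        "LongRunEmphasis": float(np.sum(R * l**2) / Nr),
        "LowGrayLevelRunEmphasis": float(np.sum(R / i**2) / Nr),
        "HighGrayLevelRunEmphasis": float(np.sum(R * i**2) / Nr),
        "GrayLevelNonUniformity": float(np.sum(r_g**2) / Nr),
        "RunLengthNonUniformity": float(np.sum(r_l**2) / Nr),
        "RunPercentage": float(Nr / np.sum(R * l)),
    }


def glrlm_features(
    roi: QuantizedROI, angles: tuple[int, ...] = (0, 45, 90, 135)
) -> list[FeatureVectorRecord]:
    """Run-length features averaged over the four principal directions."""
    per_angle = [_glrlm_feature_dict(_glrlm_single(roi, a)) for a in angles]
    per_angle = [d for d in per_angle if d]
    keys = per_angle[0].keys()
    return [
        FeatureVectorRecord(f"RLM_{k}", float(np.mean([d[k] for d in per_angle])))
        for k in keys
    ]


# --------------------------------------------------------------------------
# GLSZM


def glszm_features(roi: QuantizedROI) -> list[FeatureVectorRecord]:
    """Size-zone features; zones are 8-connected regions of equal level.

    A constant ROI is a single zone, so SizeZoneNonUniformityNormalized
    equals 1 there."""
    structure = np.ones((3, 3), dtype=int)
    zones: list[tuple[int, int]] = []  # (level, size)
    for g in range(1, roi.Ng + 1):
        where = (roi.gray_levels == g) & roi.mask
        if not where.any():
            continue
        lab, n = ndimage.label(where, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    Nz = len(zones)
    levels = np.array([g for g, _ in zones], dtype=float)
    sizes = np.array([s for _, s in zones], dtype=float)
    p = np.ones(Nz) / Nz
    mu_g = float(np.sum(p * levels))
    # zone-size marginal for the nonuniformity terms
    size_counts: dict[int, int] = {}
    level_counts: dict[int, int] = {}
    for g, s in zones:
        size_counts[s] = size_counts.get(s, 0) + 1
        level_counts[g] = level_counts.get(g, 0) + 1
    feats = {
        "SmallAreaEmphasis": float(np.mean(1.0 / sizes**2)),
        "LargeAreaEmphasis": float(np.mean(sizes**2)),
        "LowGrayLevelZoneEmphasis": float(np.mean(1.0 / levels**2)),
        "HighGrayLevelZoneEmphasis": float(np.mean(levels**2)),
        "SizeZoneNonUniformityNormalized": float(
            sum(c**2 for c in size_counts.values()) / Nz**2
        ),
        "GrayLevelNonUniformityNormalized": float(
            sum(c**2 for c in level_counts.values()) / Nz**2
        ),
        "ZoneEntropy": float(-(p * np.log2(p)).sum()),
        "GrayLevelVariance": float(np.sum(p * (levels - mu_g) ** 2)),
        "ZonePercentage": float(Nz / roi.mask.sum()),
    }
    return [FeatureVectorRecord(f"SZM_{k}", x) for k, x in feats.items()]


# --------------------------------------------------------------------------
# Gray-level difference matrix


def gldm_difference_features(
    roi: QuantizedROI,
    distance: int = 1,
    angles: tuple[int, ...] = (0, 45, 90, 135),
) -> list[FeatureVectorRecord]:
    """Histogram of absolute level differences |g(x) - g(x + d*angle)|
    over in-mask pairs: p(k), k = 0..Ng-1.

    Features: DifferenceMean = sum k p(k), DifferenceVariance,
    DifferenceEntropy (base 2), DifferenceContrast = sum k^2 p(k)."""
    h, w = roi.gray_levels.shape
    counts = np.zeros(roi.Ng)
    for a in angles:
        dr, dc = _ANGLE_OFFSETS[a]
        dr, dc = dr * distance, dc * distance
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        src = np.s_[r0:r1, c0:c1]
        dst = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = roi.mask[src] & roi.mask[dst]
        diffs = np.abs(roi.gray_levels[src] - roi.gray_levels[dst])[valid]
        counts += np.bincount(diffs, minlength=roi.Ng)[: roi.Ng]
    total = counts.sum()
    if total == 0:
        raise ValueError("zero valid pixel pairs at the requested distance")
    p = counts / total
    k = np.arange(roi.Ng, dtype=float)
    mean = float(np.sum(k * p))
    nz = p[p > 0]
    feats = {
        "DifferenceMean": mean,
        "DifferenceVariance": float(np.sum(p * (k - mean) ** 2)),
        "DifferenceEntropy": float(-(nz * np.log2(nz)).sum()),
        "DifferenceContrast": float(np.sum(k**2 * p)),
    }
    return [
        FeatureVectorRecord(f"DIF_{k_}_distance={distance}", x)
        for k_, x in feats.items()
    ]


# --------------------------------------------------------------------------
# Neighborhood matrices (Chebyshev neighborhoods of the stated distance)


def _neighborhood_means(roi: QuantizedROI, distance: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean level of in-mask Chebyshev neighbors (center
    excluded) and a validity flag (pixel in mask with >= 1 neighbor)."""
    size = 2 * distance + 1
    kernel = np.ones((size, size))
    kernel[distance, distance] = 0.0
    m = roi.mask.astype(float)
    g = roi.gray_levels.astype(float) * m
    nbr_sum = ndimage.correlate(g, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(m, kernel, mode="constant", cval=0.0)
    valid = roi.mask & (nbr_cnt > 0)
    means = np.zeros_like(g)
    means[valid] = nbr_sum[valid] / nbr_cnt[valid]
    return means, valid


def ngtdm_features(
    roi: QuantizedROI, distance: int = 1
) -> list[FeatureVectorRecord]:
    """Amadasun-King neighborhood gray-tone difference features.

    With N valid pixels, p_i the fraction at level i and
    s_i = sum over those pixels of |g - neighborhood mean|:
      Coarseness = 1 / sum_i p_i s_i            (0 if the sum is 0)
      Contrast   = [sum_ij p_i p_j (i-j)^2 / (Ngp(Ngp-1))] * [sum_i s_i / N]
      Busyness   = sum_i p_i s_i / sum_ij |i p_i - j p_j|   (0/0 -> 0)
      Complexity = sum_ij |i-j| (p_i s_i + p_j s_j) / (N (p_i + p_j))
      Strength   = sum_ij (p_i + p_j)(i-j)^2 / sum_i s_i    (0/0 -> 0)
    On a constant ROI all s_i are 0, so Complexity and Strength are 0.
    """
    means, valid = _neighborhood_means(roi, distance)
    N = valid.sum()
    if N == 0:
        raise ValueError("no valid pixels for the requested distance")
    g = roi.gray_levels
    s = np.zeros(roi.Ng + 1)
    n = np.zeros(roi.Ng + 1)
    for i in range(1, roi.Ng + 1):
        sel = valid & (g == i)
        n[i] = sel.sum()
        s[i] = np.abs(g[sel] - means[sel]).sum()
    p = n / N
    present = np.flatnonzero(p > 0)
    Ngp = len(present)
    ps = float(np.sum(p * s))

    coarseness = float(1.0 / ps) if ps > _EPS else 0.0
    if Ngp > 1:
        ii, jj = np.meshgrid(present, present, indexing="ij")
        contrast = float(
            np.sum(p[ii] * p[jj] * (ii - jj) ** 2)
            / (Ngp * (Ngp - 1))
            * (s.sum() / N)
        )
        denom_busy = float(np.sum(np.abs(ii * p[ii] - jj * p[jj])))
        busyness = float(ps / denom_busy) if denom_busy > _EPS else 0.0
        complexity = float(
            np.sum(
                np.abs(ii - jj)
                * (p[ii] * s[ii] + p[jj] * s[jj])
                / (N * (p[ii] + p[jj]))
            )
        )
        ssum = s.sum()
        strength = (
            float(np.sum((p[ii] + p[jj]) * (ii - jj) ** 2) / ssum)
            if ssum > _EPS
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    feats = {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
    return [
        FeatureVectorRecord(f"NTM_{k}_distance={distance}", x)
        for k, x in feats.items()
    ]


def dependency_features(
    roi: QuantizedROI, distance: int = 1
) -> list[FeatureVectorRecord]:
    """Neighborhood dependency features.

    For each in-mask pixel, the dependence is 1 + the count of in-mask
    Chebyshev neighbors sharing its quantized level; P(i, j) counts pixels
    with level i and dependence j, normalized to p."""
    size = 2 * distance + 1
    kernel = np.ones((size, size))
    kernel[distance, distance] = 0.0
    deps: list[tuple[int, int]] = []
    g = roi.gray_levels
    same_counts = np.zeros(g.shape)
    for i in range(1, roi.Ng + 1):
        sel = ((g == i) & roi.mask).astype(float)
        same = ndimage.correlate(sel, kernel, mode="constant", cval=0.0)
        same_counts[(g == i) & roi.mask] = same[(g == i) & roi.mask]
    rows, cols = np.nonzero(roi.mask)
    levels = g[rows, cols].astype(float)
    j = same_counts[rows, cols] + 1.0
    Nz = len(levels)
    p = np.ones(Nz) / Nz
    mu_j = float(np.mean(j))
    mu_g = float(np.mean(levels))
    # dependence-size histogram entropy
    pairs: dict[tuple[float, float], int] = {}
    for gi, ji in zip(levels, j):
        pairs[(gi, ji)] = pairs.get((gi, ji), 0) + 1
    q = np.array(list(pairs.values()), dtype=float) / Nz
    feats = {
        "SmallDependenceEmphasis": float(np.mean(1.0 / j**2)),
        "LargeDependenceEmphasis": float(np.mean(j**2)),
        "DependenceVariance": float(np.mean((j - mu_j) ** 2)),
        "DependenceEntropy": float(-(q * np.log2(q)).sum()),
        "GrayLevelVariance": float(np.mean((levels - mu_g) ** 2)),
    }
    return [
        FeatureVectorRecord(f"NDM_{k}_distance={distance}", x)
        for k, x in feats.items()
    ]


# --------------------------------------------------------------------------
# Shape


def shape_features(
    mask: np.ndarray, pixel_spacing: tuple[float, float] = (1.0, 1.0)
) -> list[FeatureVectorRecord]:
    """Geometry of the mask's (largest) connected component.

    Perimeter is scikit-image's weighted boundary-pixel estimator;
    circularity = 4 pi A / P^2 with that estimator.  Elongation is the
    major/minor axis-length ratio (1 for degenerate shapes).  Spacing is
    assumed isotropic for the perimeter (mean of the two spacings)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab = sk_label(mask)
    props = regionprops(lab)
    if len(props) > 1:
        logger.warning("mask has %d components; using the largest", len(props))
    region = max(props, key=lambda r: r.area)
    sy, sx = pixel_spacing
    area = float(region.area) * sy * sx
    perim = float(region.perimeter) * 0.5 * (sy + sx)
    circ = float(4 * np.pi * area / perim**2) if perim > 0 else 0.0
    major = float(region.axis_major_length) * 0.5 * (sy + sx)
    minor = float(region.axis_minor_length) * 0.5 * (sy + sx)
    elong = float(major / minor) if minor > _EPS else 1.0
    feats = {
        "Area": area,
        "Perimeter": perim,
        "Circularity": circ,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Elongation": elong,
    }
    return [FeatureVectorRecord(f"SHAPE_{k}", x) for k, x in feats.items()]


# --------------------------------------------------------------------------
# Orchestration


_FAMILY_FUNCS = {
    "FOD": lambda roi, raw, d: first_order_features(roi, raw),
    "COM": lambda roi, raw, d: glcm_features(roi, distance=d),
    "RLM": lambda roi, raw, d: glrlm_features(roi),
    "DIF": lambda roi, raw, d: gldm_difference_features(roi, distance=d),
    "SZM": lambda roi, raw, d: glszm_features(roi),
    "NTM": lambda roi, raw, d: ngtdm_features(roi, distance=d),
    "NDM": lambda roi, raw, d: dependency_features(roi, distance=d),
}
_DISTANCE_FAMILIES = {"COM", "DIF", "NTM", "NDM"}


@dataclass
class ExtractionConfig:
    Ng: int = 32
    distances: tuple[int, ...] = (1, 3)
    families: tuple[str, ...] = ("FOD", "COM", "RLM", "DIF", "SZM", "NTM", "NDM")
    include_shape: bool = True
    log_sigmas: tuple[float, ...] = (1.0,)
    wavelet: bool = True
    contourlet: bool = True
    levels: int = 3


def _family_records(
    image: np.ndarray,
    mask: np.ndarray,
    config: ExtractionConfig,
    prefix: str,
    suffix: str = "",
) -> list[FeatureVectorRecord]:
    roi = quantize(image, mask, config.Ng)
    raw = image[mask]
    out: list[FeatureVectorRecord] = []
    for fam in config.families:
        func = _FAMILY_FUNCS[fam]
        dists = config.distances if fam in _DISTANCE_FAMILIES else (1,)
        for d in dists:
            try:
                recs = func(roi, raw, d)
            except ValueError as exc:
                logger.warning("%s%s %s: %s", prefix, suffix, fam, exc)
                continue
            for r in recs:
                out.append(
                    FeatureVectorRecord(prefix + r.feature_name + suffix, r.value)
                )
    return out


def _resample_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor downscale of the ROI mask to a subband's shape."""
    h, w = shape
    rows = np.clip(np.round(np.linspace(0, mask.shape[0] - 1, h)).astype(int), 0, None)
    cols = np.clip(np.round(np.linspace(0, mask.shape[1] - 1, w)).astype(int), 0, None)
    return mask[np.ix_(rows, cols)]


def extract_all(
    image: np.ndarray, mask: np.ndarray, config: ExtractionConfig | None = None
) -> list[FeatureVectorRecord]:
    """Every enabled family on the raw ROI and on each enabled subband.

    Output order is deterministic: raw, LoG (per sigma), wavelet subbands
    1..9, contourlet subbands 1..16, then shape.  Degenerate families on a
    subband are logged and skipped, never fatal."""
    config = config or ExtractionConfig()
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    records: list[FeatureVectorRecord] = []
    records += _family_records(image, mask, config, "")
    for sigma in config.log_sigmas:
        try:
            filtered = log_filter(image, sigma)
        except ValueError as exc:
            logger.warning("LoG sigma=%g skipped: %s", sigma, exc)
            continue
        records += _family_records(
            filtered, mask, config, "LoG-", f"_sigma={sigma:g}"
        )
    if config.wavelet:
        bands = wavelet_decompose(image, config.levels)
        for comp in bands.components:
            small = _resample_mask(mask, comp.image.shape)
            if small.sum() < 2:
                logger.warning("wavelet component %d: mask too small", comp.number)
                continue
            records += _family_records(
                comp.image, small, config, "CMS-W", f"_component={comp.number}"
            )
    if config.contourlet:
        bands = contourlet_decompose(image, config.levels)
        for comp in bands.components:
            small = _resample_mask(mask, comp.image.shape)
            if small.sum() < 2:
                logger.warning("contourlet component %d: mask too small", comp.number)
                continue
            records += _family_records(
                comp.image, small, config, "CMS-C", f"_component={comp.number}"
            )
    if config.include_shape:
        records += shape_features(mask)
    names = [r.feature_name for r in records]
    if len(set(names)) != len(names):
        raise RuntimeError("duplicate feature names in extraction output")
    return records
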