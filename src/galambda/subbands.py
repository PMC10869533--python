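"""Filtering front end: Laplacian of Gaussian, 3-level wavelet and 3-level
contourlet decompositions, with a fixed component-numbering convention.

Numbering convention (shared by feature names downstream):

* wavelet: components 1-3 are the level-1 (finest) horizontal, vertical
  and diagonal details; 4-6 the level-2 details; 7-9 the level-3 details;
* contourlet: components 1-8 are the eight level-1 directional subbands,
  9-12 the four level-2 subbands, 13-16 the four level-3 subbands.

The wavelet uses an orthogonal Daubechies-4 pair with periodized boundary
handling, so the transform is energy-preserving and exactly invertible and
level-k bands have sides ``side / 2^k``.  The contourlet is implemented as
a Laplacian pyramid (exactly invertible by construction) whose bandpass
image at each level is split into directional subbands by a partition of
the frequency plane into angular wedges; the wedge masks sum to one, so
the directional subbands of a level sum back to the bandpass image.  Only
the forward transform is used for feature extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

__all__ = [
    "Subband",
    "SubbandSet",
    "log_filter",
    "wavelet_decompose",
    "contourlet_decompose",
    "laplacian_pyramid",
    "reconstruct_pyramid",
]

_WAVELET = "db4"
_WT_MODE = "periodization"
_ORIENT_NAMES = {"H": "horizontal", "V": "vertical", "D": "diagonal"}


@dataclass(frozen=True)
class Subband:
    number: int  # 1-based, per the numbering convention
    level: int  # 1 = finest
    orientation: str
    image: np.ndarray


@dataclass(frozen=True)
class SubbandSet:
    source: str
    transform: str  # "wavelet" | "contourlet" | "log"
    components: tuple[Subband, ...]
    approximation: np.ndarray | None

    def __post_init__(self) -> None:
        numbers = [c.number for c in self.components]
        if numbers != list(range(1, len(numbers) + 1)):
            raise ValueError("component numbers must be contiguous from 1")

    def component(self, number: int) -> Subband:
        return self.components[number - 1]


# --------------------------------------------------------------------------
# Laplacian of Gaussian


def log_kernel(sigma: float, radius: int | None = None) -> np.ndarray:
    """Sampled continuous LoG kernel, truncated at 3 sigma and adjusted to
    zero sum (so the response to a constant image is exactly zero)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius is None:
        radius = int(np.ceil(3 * sigma))
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    g = np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    k = (r2 - 2 * sigma**2) / sigma**4 * g
    return k - k.mean()


def log_filter(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Convolve with the zero-sum sampled LoG kernel (reflect boundary).

    Linear in the input and of the same spatial dimensions."""
    image = np.asarray(image, dtype=float)
    k = log_kernel(sigma)
    r = k.shape[0] // 2
    if min(image.shape) < 2 * r + 1:
        raise ValueError(f"image smaller than the {2*r+1}-pixel kernel support")
    return ndimage.convolve(image, k, mode="reflect")


# --------------------------------------------------------------------------
# Wavelet


def wavelet_decompose(
    image: np.ndarray, levels: int = 3, wavelet: str = _WAVELET
) -> SubbandSet:
    """3-level separable DWT; returns 3*levels numbered detail components
    plus the final approximation.  Exactly invertible; orthogonal, so the
    coefficient energy equals the image energy."""
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 2**levels:
        raise ValueError(f"image too small for {levels} levels")
    with warnings.catch_warnings():
        # pywt flags boundary effects for deep levels on small images;
        # periodized db4 still reconstructs and conserves energy exactly
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(image, wavelet, mode=_WT_MODE, level=levels)
    # coeffs = [cA_L, (cH_L, cV_L, cD_L), ..., (cH_1, cV_1, cD_1)]
    approx = coeffs[0]
    components: list[Subband] = []
    number = 1
    for level in range(1, levels + 1):
        cH, cV, cD = coeffs[levels + 1 - level]
        for tag, band in (("H", cH), ("V", cV), ("D", cD)):
            components.append(
                Subband(
                    number=number,
                    level=level,
                    orientation=_ORIENT_NAMES[tag],
                    image=np.asarray(band, dtype=float),
                )
            )
            number += 1
    return SubbandSet(
        source="", transform="wavelet", components=tuple(components),
        approximation=np.asarray(approx, dtype=float),
    )


def wavelet_reconstruct(bands: SubbandSet, wavelet: str = _WAVELET) -> np.ndarray:
    """Inverse of :func:`wavelet_decompose` (for the round-trip check)."""
    levels = max(c.level for c in bands.components)
    coeffs: list = [bands.approximation]
    for level in range(levels, 0, -1):
        per_level = [c for c in bands.components if c.level == level]
        by_orient = {c.orientation: c.image for c in per_level}
        coeffs.append(
            (by_orient["horizontal"], by_orient["vertical"], by_orient["diagonal"])
        )
    return pywt.waverec2(coeffs, wavelet, mode=_WT_MODE)


# --------------------------------------------------------------------------
# Contourlet: Laplacian pyramid + angular-wedge directional filter bank


# Burt-Adelson binomial kernel; both polyphase branches of the matching
# interpolator have unit weight sums, so constants are reproduced exactly
_PYR_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _downsample(img: np.ndarray) -> np.ndarray:
    sm = ndimage.correlate1d(img, _PYR_KERNEL, axis=0, mode="reflect")
    sm = ndimage.correlate1d(sm, _PYR_KERNEL, axis=1, mode="reflect")
    return sm[::2, ::2]


def _up_axis0(x: np.ndarray, n_out: int) -> np.ndarray:
    """Polyphase 2x interpolation along axis 0: even outputs from the
    (1, 6, 1)/8 branch, odd outputs from the (4, 4)/8 branch of the
    zero-stuffed binomial filter (each branch sums to 1)."""
    xp = np.concatenate([x[:1], x, x[-1:]], axis=0)  # edge pad by one
    even = (xp[:-2] + 6.0 * xp[1:-1] + xp[2:]) / 8.0
    odd = (xp[1:-1] + xp[2:]) / 2.0
    y = np.empty((2 * x.shape[0],) + x.shape[1:])
    y[0::2] = even
    y[1::2] = odd
    return y[:n_out]


def _upsample(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    up = _up_axis0(img, shape[0])
    up = np.swapaxes(_up_axis0(np.swapaxes(up, 0, 1), shape[1]), 0, 1)
    return up


def laplacian_pyramid(
    image: np.ndarray, levels: int = 3
) -> tuple[list[np.ndarray], np.ndarray]:
    """Bandpass images (finest first) plus the residual lowpass.

    Exactly invertible by construction: ``G_k = bandpass_k +
    expand(G_{k+1})``."""
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 2**levels:
        raise ValueError(f"image too small for {levels} levels")
    bandpass = []
    current = image
    for _ in range(levels):
        low = _downsample(current)
        bandpass.append(current - _upsample(low, current.shape))
        current = low
    return bandpass, current


def reconstruct_pyramid(
    bandpass: list[np.ndarray], lowpass: np.ndarray
) -> np.ndarray:
    """Exact inverse of :func:`laplacian_pyramid`."""
    current = lowpass
    for band in reversed(bandpass):
        current = band + _upsample(current, band.shape)
    return current


def _wedge_masks(shape: tuple[int, int], n_directions: int) -> np.ndarray:
    """Binary angular wedge masks over the FFT plane.

    Directions partition the orientation half-circle [0, pi); each
    frequency bin belongs to exactly one wedge, and the map is symmetric
    under f -> -f, so masked spectra of real images invert to real
    subbands.  The masks sum to one everywhere.
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    theta = np.mod(np.arctan2(fy, fx), np.pi)  # orientation in [0, pi)
    edges = np.linspace(0, np.pi, n_directions + 1)
    idx = np.clip(np.digitize(theta, edges) - 1, 0, n_directions - 1)
    masks = np.stack([(idx == d) for d in range(n_directions)]).astype(float)
    return masks


def _directional_split(band: np.ndarray, n_directions: int) -> list[np.ndarray]:
    F = np.fft.fft2(band)
    masks = _wedge_masks(band.shape, n_directions)
    return [np.real(np.fft.ifft2(F * m)) for m in masks]


def contourlet_decompose(
    image: np.ndarray,
    levels: int = 3,
    directions_per_level: tuple[int, ...] = (8, 4, 4),
) -> SubbandSet:
    """Laplacian pyramid + directional split: 8 subbands at level 1, four
    at levels 2 and 3 by default (16 detail components total)."""
    directions_per_level = tuple(directions_per_level)
    if len(directions_per_level) != levels:
        raise ValueError("need one direction count per level")
    for d in directions_per_level:
        if d < 1 or (d & (d - 1)):
            raise ValueError("direction counts must be powers of two")
    bandpass, lowpass = laplacian_pyramid(image, levels)
    components: list[Subband] = []
    number = 1
    for level, (band, ndir) in enumerate(zip(bandpass, directions_per_level), start=1):
        for d, sub in enumerate(_directional_split(band, ndir)):
            lo, hi = d * 180.0 / ndir, (d + 1) * 180.0 / ndir
            components.append(
                Subband(
                    number=number,
                    level=level,
                    orientation=f"{lo:.0f}-{hi:.0f}deg",
                    image=sub,
                )
            )
            number += 1
    return SubbandSet(
        source="", transform="contourlet", components=tuple(components),
        approximation=lowpass,
    )
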