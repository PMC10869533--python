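"""Synthetic labeled feature tables and small textured images.

Real radiomic feature tables in this problem sit in the ``n << p`` regime
(on the order of a hundred training samples against thousands of extracted
features), with a sparse informative signal buried among blocks of highly
correlated features (texture features computed on overlapping subbands are
strongly redundant).  The generator emulates exactly those properties:

* features are block-correlated standard normals (Gaussian copula with
  identity marginals — blocks share a compound-symmetric correlation rho);
* the binary outcome follows a logistic model on a small informative
  subset, so any planted effect is on the log-odds scale;
* ground-truth informative indices are returned for recovery scoring.

Small textured images (constant, checkerboard, gradient, correlated noise)
with full masks serve as fixtures for the feature-extraction front end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datamodel import FeatureTable

__all__ = ["SyntheticSpec", "generate_feature_table", "generate_texture_image"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    ``block_structure`` is a list of ``(size, rho)`` pairs; features are
    assigned to blocks from the left, remaining features are independent.
    ``effect_sizes`` are log-odds slopes of the informative features.
    """

    n_samples: int = 180
    n_features: int = 300
    n_informative: int = 10
    effect_sizes: tuple[float, ...] | None = None
    block_structure: tuple[tuple[int, float], ...] = ()
    intercept: float = 0.0
    seed: int = 0

    def resolved_effects(self) -> np.ndarray:
        if self.effect_sizes is not None:
            eff = np.asarray(self.effect_sizes, dtype=float)
            if eff.shape != (self.n_informative,):
                raise ValueError("effect_sizes length must equal n_informative")
            return eff
        # default magnitude 1.5 with alternating signs
        signs = np.where(np.arange(self.n_informative) % 2 == 0, 1.0, -1.0)
        return 1.5 * signs

    def validate(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative exceeds n_features")
        if sum(s for s, _ in self.block_structure) > self.n_features:
            raise ValueError("block sizes exceed n_features")
        for size, rho in self.block_structure:
            if not (0 <= rho < 1):
                raise ValueError("block correlation must lie in [0,1)")
            if size < 1:
                raise ValueError("block size must be positive")


def generate_feature_table(spec: SyntheticSpec) -> tuple[FeatureTable, np.ndarray]:
    """Draw a labeled table; returns ``(table, informative_indices)``.

    Features are standard normal with compound-symmetric correlation inside
    each declared block.  Labels are Bernoulli with success probability
    ``sigmoid(intercept + X[:, informative] @ effects)``.  Informative
    columns are chosen uniformly without replacement (deterministic given
    the seed), so they may or may not fall inside correlated blocks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features

    X = rng.standard_normal((n, p))
    pos = 0
    for size, rho in spec.block_structure:
        if size > 1 and rho > 0:
            # compound symmetry via a shared latent factor:
            # z_j = sqrt(rho) * u + sqrt(1-rho) * e_j  has corr(z_j, z_k) = rho
            u = rng.standard_normal((n, 1))
            X[:, pos : pos + size] = np.sqrt(rho) * u + np.sqrt(1 - rho) * X[
                :, pos : pos + size
            ]
        pos += size

    informative = np.sort(rng.choice(p, size=spec.n_informative, replace=False))
    eta = spec.intercept + X[:, informative] @ spec.resolved_effects()
    prob = 1.0 / (1.0 + np.exp(-eta))
    labels = (rng.random(n) < prob).astype(int)

    names = tuple(f"f{j:04d}" for j in range(p))
    ids = tuple(f"s{i:04d}" for i in range(n))
    return FeatureTable(X, names, labels, ids), informative


def generate_texture_image(
    kind: str,
    size: tuple[int, int] = (32, 32),
    params: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a deterministic 8-bit test image with a full ROI mask.

    Kinds: ``constant`` (params: value), ``checker`` (params: period, lo,
    hi), ``gradient`` (left-to-right ramp), ``correlated-noise`` (params:
    smooth_sigma).  Pixel values lie in [0, 255].
    """
    params = dict(params or {})
    h, w = size
    if h < 8 or w < 8:
        raise ValueError("image size must be at least 8x8")
    rng = np.random.default_rng(seed)

    if kind == "constant":
        img = np.full((h, w), float(params.get("value", 128.0)))
    elif kind == "checker":
        period = int(params.get("period", 2))
        lo, hi = float(params.get("lo", 0.0)), float(params.get("hi", 255.0))
        rr, cc = np.indices((h, w))
        img = np.where(((rr // period) + (cc // period)) % 2 == 0, lo, hi)
    elif kind == "gradient":
        col = np.linspace(0.0, 255.0, w)
        img = np.tile(col, (h, 1))
    elif kind == "correlated-noise":
        sigma = float(params.get("smooth_sigma", 2.0))
        raw = rng.standard_normal((h, w))
        sm = ndimage.gaussian_filter(raw, sigma, mode="reflect")
        lo, hi = sm.min(), sm.max()
        img = (sm - lo) / (hi - lo) * 255.0 if hi > lo else np.full((h, w), 128.0)
    else:
        raise ValueError(f"unknown kind {kind!r}")

    img = np.clip(img, 0.0, 255.0)
    mask = np.ones((h, w), dtype=bool)
    return img, mask
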