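"""Independent oracles and small utilities shared across the test suite.

Everything here is deliberately written along a *different* route than
the implementation it checks: exhaustive enumeration instead of
dynamic programming, pairwise distances instead of distance
transforms, scalar loops instead of vectorized sweeps.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import ndimage

from spinecarve.hmc import HMCParams


def gauss_pdf(y: float, mu: float, sigma: float) -> float:
    return math.exp(-0.5 * ((y - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


def joint_probability(xs, y, params: HMCParams) -> float:
    """p(x, y) of the HMC-IN model, term by term."""
    pr = params.pi[xs[0]] * gauss_pdf(y[0], params.mu[xs[0]], params.sigma[xs[0]])
    for n in range(1, len(xs)):
        pr *= params.Pi[xs[n - 1]][xs[n]] * gauss_pdf(
            y[n], params.mu[xs[n]], params.sigma[xs[n]]
        )
    return pr


def enumerate_posterior(params: HMCParams, y) -> np.ndarray:
    """Posterior marginals by exhaustive enumeration of all 2^N sequences."""
    N = len(y)
    post = np.zeros((N, 2))
    for xs in itertools.product((0, 1), repeat=N):
        pr = joint_probability(xs, y, params)
        for n, v in enumerate(xs):
            post[n, v] += pr
    return post / post.sum(axis=1, keepdims=True)


def enumerate_sequence_posterior(params: HMCParams, y) -> dict[tuple, float]:
    """p(x | y) for every full sequence, by enumeration."""
    probs = {
        xs: joint_probability(xs, y, params)
        for xs in itertools.product((0, 1), repeat=len(y))
    }
    total = sum(probs.values())
    return {xs: p / total for xs, p in probs.items()}


def random_params(rng: np.random.Generator) -> HMCParams:
    """A random valid two-class parameter set."""
    pi0 = rng.uniform(0.1, 0.9)
    p00 = rng.uniform(0.05, 0.95)
    p11 = rng.uniform(0.05, 0.95)
    mu = sorted(rng.uniform(-2, 2, size=2))
    sigma = rng.uniform(0.2, 1.5, size=2)
    return HMCParams(
        (pi0, 1 - pi0),
        ((p00, 1 - p00), (1 - p11, p11)),
        tuple(mu),
        tuple(sigma),
    )


def brute_erode(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Erosion oracle: a voxel survives iff no background voxel (array
    boundary counts as background) lies within the physical radius.
    Pairwise distances, no distance transform."""
    spacing = np.asarray(spacing, float)
    padded = np.pad(mask, 1, constant_values=False)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    out = np.zeros(padded.shape, dtype=bool)
    r2 = radius_mm**2 + 1e-9
    for vox in fg:
        d2 = (((bg - vox) * spacing) ** 2).sum(axis=1)
        out[tuple(vox)] = d2.min() > r2
    return out[1:-1, 1:-1, 1:-1]


def brute_dilate(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Dilation oracle: any voxel within the physical radius of the set."""
    spacing = np.asarray(spacing, float)
    fg = np.argwhere(mask)
    out = np.zeros(mask.shape, dtype=bool)
    r2 = radius_mm**2 + 1e-9
    for vox in np.ndindex(mask.shape):
        d2 = (((fg - np.asarray(vox)) * spacing) ** 2).sum(axis=1)
        out[vox] = d2.min() <= r2
    return out


def random_roi(rng: np.random.Generator, shape=(24, 24, 6)) -> np.ndarray:
    """A random blobby mask (thresholded smoothed noise)."""
    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    mask = field > np.quantile(field, 0.6)
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return mask


def main_component_dice(pred, truth) -> float:
    """Dice of the predicted connected component that best overlaps the
    ground truth (the component containing the vertebral body)."""
    comp, n = ndimage.label(pred.data, structure=np.ones((3, 3, 3), bool))
    if n == 0:
        return 0.0
    best = max(range(1, n + 1), key=lambda c: int(np.sum((comp == c) & truth.data)))
    p = comp == best
    tp = int((p & truth.data).sum())
    return 2 * tp / (int(p.sum()) + int(truth.data.sum()))
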