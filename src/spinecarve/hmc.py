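"""Two-class hidden Markov chain with independent Gaussian noise.

Model (HMC-IN): the hidden class sequence ``X = (X_1..X_N)`` over
``Omega = {omega0 (non-vertebra), omega1 (vertebra)}`` is a homogeneous
Markov chain with initial law ``pi`` and transition matrix ``Pi``;
observations are conditionally independent given their own class with
Gaussian emissions ``Y_n | X_n = omega_i ~ N(mu_i, sigma_i)``.

Provided here:

* exact posterior marginals ``xi_n = p(x_n | y)`` by the scaled
  forward–backward recursions (per-step normalization, safe for chains
  of 10^6+ elements);
* the MPM decision (per-site argmax of ``xi``, the Bayes rule for the
  per-site error rate);
* posterior sampling of complete class sequences through the posterior
  transition probabilities — the S-step of SEM;
* maximum-likelihood estimation from complete data — the M-step;
* SEM: iterate E (forward–backward), S (sample a sequence), M
  (complete-data ML), monitoring convergence through the disagreement
  fraction between consecutive on-the-fly MPM classifications.

``ClassSequence`` is realized as an integer numpy array over {0, 1} and
``PosteriorMarginals`` as an (N, 2) float array with rows summing to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .errors import DegenerateClassError, DegenerateInputError

__all__ = [
    "HMCParams",
    "SEMTrace",
    "forward_backward",
    "mpm_classify",
    "sample_posterior_chain",
    "ml_estimate",
    "convergence_rate",
    "sem_estimate",
    "simulate_hmc_chain",
]

SIGMA_FLOOR = 1e-4  # prevents Gaussian collapse on (near-)noiseless data


@dataclass(frozen=True)
class HMCParams:
    """Theta = {pi_i, pi_ij, mu_i, sigma_i} for the two classes."""

    pi: tuple[float, float]
    Pi: tuple[tuple[float, float], tuple[float, float]]
    mu: tuple[float, float]
    sigma: tuple[float, float]

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, float)
        Pi = np.asarray(self.Pi, float)
        if pi.shape != (2,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError(f"pi must be a distribution over 2 classes: {self.pi}")
        if Pi.shape != (2, 2) or np.any(Pi < 0) or np.any(np.abs(Pi.sum(1) - 1) > 1e-8):
            raise ValueError(f"Pi rows must be distributions: {self.Pi}")
        if len(self.mu) != 2:
            raise ValueError("mu must have 2 entries")
        if len(self.sigma) != 2 or any(s <= 0 for s in self.sigma):
            raise ValueError(f"sigma must be 2 positive reals: {self.sigma}")
        object.__setattr__(self, "pi", tuple(float(v) for v in self.pi))
        object.__setattr__(self, "Pi", tuple(tuple(float(v) for v in row)
                                             for row in self.Pi))
        object.__setattr__(self, "mu", tuple(float(v) for v in self.mu))
        object.__setattr__(self, "sigma", tuple(float(v) for v in self.sigma))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (np.asarray(self.pi), np.asarray(self.Pi),
                np.asarray(self.mu), np.asarray(self.sigma))


def _emission_densities(y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Gaussian emission densities f[n, i] = N(y_n; mu_i, sigma_i)."""
    z = (y[:, None] - mu[None, :]) / sigma[None, :]
    f = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sigma[None, :])
    # keep rows strictly positive so normalized recursions stay defined
    return np.maximum(f, 1e-300)


@njit(cache=True)
def _forward(f, pi, Pi):  # pragma: no cover - exercised via forward_backward
    N = f.shape[0]
    alpha = np.empty((N, 2))
    a0 = pi[0] * f[0, 0]
    a1 = pi[1] * f[0, 1]
    c = a0 + a1
    alpha[0, 0] = a0 / c
    alpha[0, 1] = a1 / c
    for n in range(1, N):
        a0 = (alpha[n - 1, 0] * Pi[0, 0] + alpha[n - 1, 1] * Pi[1, 0]) * f[n, 0]
        a1 = (alpha[n - 1, 0] * Pi[0, 1] + alpha[n - 1, 1] * Pi[1, 1]) * f[n, 1]
        c = a0 + a1
        if c <= 0.0:
            a0, a1, c = 0.5, 0.5, 1.0
        alpha[n, 0] = a0 / c
        alpha[n, 1] = a1 / c
    return alpha


@njit(cache=True)
def _backward(f, Pi):  # pragma: no cover - exercised via forward_backward
    N = f.shape[0]
    beta = np.empty((N, 2))
    beta[N - 1, 0] = 1.0
    beta[N - 1, 1] = 1.0
    for n in range(N - 2, -1, -1):
        b0 = (Pi[0, 0] * f[n + 1, 0] * beta[n + 1, 0]
              + Pi[0, 1] * f[n + 1, 1] * beta[n + 1, 1])
        b1 = (Pi[1, 0] * f[n + 1, 0] * beta[n + 1, 0]
              + Pi[1, 1] * f[n + 1, 1] * beta[n + 1, 1])
        c = b0 + b1
        if c <= 0.0:
            b0, b1, c = 0.5, 0.5, 1.0
        beta[n, 0] = b0 / c
        beta[n, 1] = b1 / c
    return beta


@njit(cache=True)
def _sample_posterior(u, f, Pi, beta, p1_0):  # pragma: no cover
    N = f.shape[0]
    x = np.empty(N, dtype=np.int8)
    x[0] = 0 if u[0] < p1_0 else 1
    for n in range(1, N):
        i = x[n - 1]
        q0 = Pi[i, 0] * f[n, 0] * beta[n, 0]
        q1 = Pi[i, 1] * f[n, 1] * beta[n, 1]
        s = q0 + q1
        p0 = 0.5 if s <= 0.0 else q0 / s
        x[n] = 0 if u[n] < p0 else 1
    return x


@njit(cache=True)
def _simulate_states(u, pi, Pi):  # pragma: no cover
    N = u.shape[0]
    x = np.empty(N, dtype=np.int8)
    x[0] = 0 if u[0] < pi[0] else 1
    for n in range(1, N):
        x[n] = 0 if u[n] < Pi[x[n - 1], 0] else 1
    return x


def forward_backward(
    params: HMCParams, y: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward pass.

    Returns ``(alpha, beta, xi)`` where ``alpha`` and ``beta`` are the
    per-step normalized forward/backward variables and ``xi[n]`` the
    posterior marginal ``p(x_n | y)``. The per-step rescaling cancels in
    ``xi`` and in the posterior transition probabilities, so the
    contract is identical to the raw recursions while remaining finite
    for arbitrarily long chains.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    if y.ndim != 1 or len(y) < 1:
        raise ValueError("y must be a non-empty 1D sequence")
    pi, Pi, mu, sigma = params.arrays()
    f = _emission_densities(y, mu, sigma)
    alpha = _forward(f, pi, Pi)
    beta = _backward(f, Pi)
    xi = alpha * beta
    xi /= xi.sum(axis=1, keepdims=True)
    return alpha, beta, xi


def mpm_classify(xi: np.ndarray) -> np.ndarray:
    """Per-site argmax of the posterior marginals; ties go to omega0."""
    xi = np.asarray(xi)
    return (xi[:, 1] > xi[:, 0]).astype(np.int8)


def sample_posterior_chain(
    params: HMCParams,
    y: np.ndarray,
    beta: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw a complete class sequence from p(x | y).

    Samples ``x_1 ~ p(x_1 | y)`` then sequentially
    ``x_n ~ p(x_n | x_{n-1}, y)`` through the posterior transition
    probabilities (transition x emission x backward, normalized).
    ``beta`` may be passed from a previous :func:`forward_backward` on
    the same inputs to avoid recomputation.
    """
    rng = np.random.default_rng(rng)
    y = np.ascontiguousarray(y, dtype=np.float64)
    pi, Pi, mu, sigma = params.arrays()
    f = _emission_densities(y, mu, sigma)
    if beta is None:
        beta = _backward(f, Pi)
    a0 = pi[0] * f[0, 0] * beta[0, 0]
    a1 = pi[1] * f[0, 1] * beta[0, 1]
    p1_0 = 0.5 if a0 + a1 <= 0 else a0 / (a0 + a1)
    u = rng.random(len(y))
    return _sample_posterior(u, f, Pi, np.ascontiguousarray(beta), p1_0)


def ml_estimate(
    x: np.ndarray, y: np.ndarray, sigma_floor: float = SIGMA_FLOOR
) -> HMCParams:
    """Complete-data maximum-likelihood estimate of Theta.

    Transition probabilities are row-normalized transition counts;
    means and standard deviations are the per-class sample statistics
    of ``y``. Because a single ``x_1`` observation makes the initial
    law degenerate, ``pi`` is estimated as the empirical class
    frequency of the whole sequence (homogeneous-chain reading; only
    the chain ends are affected). Raises
    :class:`~spinecarve.errors.DegenerateClassError` when a class is
    absent so SEM can resample.
    """
    x = np.asarray(x).astype(np.int64)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    counts = np.bincount(x, minlength=2)
    if np.any(counts == 0):
        missing = int(np.flatnonzero(counts == 0)[0])
        raise DegenerateClassError(f"class omega{missing} absent from sequence")

    pi = counts / counts.sum()
    trans = np.bincount(2 * x[:-1] + x[1:], minlength=4).reshape(2, 2).astype(float)
    row = trans.sum(axis=1, keepdims=True)
    Pi = np.where(row > 0, trans / np.maximum(row, 1), 0.5)

    mu = np.bincount(x, weights=y, minlength=2) / counts
    var = np.bincount(x, weights=(y - mu[x]) ** 2, minlength=2) / counts
    sigma = np.maximum(np.sqrt(var), sigma_floor)
    return HMCParams(tuple(pi), tuple(map(tuple, Pi)), tuple(mu), tuple(sigma))


def convergence_rate(xhat_k: np.ndarray, xhat_prev: np.ndarray) -> float:
    """Disagreement fraction between two consecutive classifications."""
    a = np.asarray(xhat_k)
    b = np.asarray(xhat_prev)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    return float(np.mean(np.abs(a.astype(float) - b.astype(float))))


@dataclass
class SEMTrace:
    """Per-iteration record of the SEM run."""

    params: list[HMCParams] = field(default_factory=list)
    epsilon: list[float | None] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.params)


def _simple_init(y: np.ndarray) -> HMCParams:
    """Class-separating initialization for [0, 1]-normalized data:
    mu = (0.25, 0.75), shared sigma from the whole sequence, uniform
    initial and transition laws."""
    s = max(float(np.std(y)), SIGMA_FLOOR)
    return HMCParams((0.5, 0.5), ((0.5, 0.5), (0.5, 0.5)), (0.25, 0.75), (s, s))


def sem_estimate(
    y: np.ndarray,
    init: HMCParams | str = "simple",
    eps_threshold: float = 0.01,
    max_iters: int = 50,
    rng_seed: int | np.random.Generator | None = None,
    min_iters: int = 3,
) -> tuple[HMCParams, SEMTrace]:
    """Stochastic EM estimation of the HMC-IN parameters.

    Each iteration runs forward–backward under the current Theta,
    records the on-the-fly MPM classification, samples a complete class
    sequence from the posterior (S-step) and re-estimates Theta by
    complete-data ML (M-step). The loop stops when the disagreement
    fraction between consecutive classifications drops below
    ``eps_threshold`` (default 1 %) or after ``max_iters`` iterations.

    The convergence test is only armed after ``min_iters`` S/M
    iterations (a short burn-in, as customary for stochastic EM):
    when the initializer already classifies the data well the churn
    statistic is tiny from the first comparison onward even though the
    parameter estimate — built from a posterior sample drawn under the
    crude initial parameters — is still far from its fixed point.

    ``init`` is either explicit reference parameters (e.g. calibrated
    on another vertebra of the same patient) or ``"simple"``, which
    assumes ``y`` normalized to [0, 1]. Stochastic steps are driven by
    ``rng_seed`` only.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("y must be a 1D sequence of length >= 2")
    if np.ptp(y) == 0:
        raise DegenerateInputError("SEM needs non-constant observations")
    rng = np.random.default_rng(rng_seed)
    theta = _simple_init(y) if isinstance(init, str) else init

    trace = SEMTrace()
    xhat_prev: np.ndarray | None = None
    for k in range(max_iters):
        _, beta, xi = forward_backward(theta, y)
        xhat = mpm_classify(xi)
        eps = None if xhat_prev is None else convergence_rate(xhat, xhat_prev)
        trace.params.append(theta)
        trace.epsilon.append(eps)
        if eps is not None and eps < eps_threshold and k >= min_iters:
            return theta, trace
        new_theta = None
        for _attempt in range(3):
            x_sim = sample_posterior_chain(theta, y, beta=beta, rng=rng)
            try:
                new_theta = ml_estimate(x_sim, y)
                break
            except DegenerateClassError:
                continue
        if new_theta is None:
            trace.warnings.append(
                "S-step degenerate three times; stopping with last valid Theta"
            )
            return theta, trace
        theta = new_theta
        xhat_prev = xhat
    return theta, trace


def simulate_hmc_chain(
    params: HMCParams, N: int, rng_seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (x, y) from the HMC-IN model; reproducible given a seed."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(rng_seed)
    pi, Pi, mu, sigma = params.arrays()
    x = _simulate_states(rng.random(N), pi, Pi)
    y = rng.normal(mu[x], sigma[x])
    return x, y
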