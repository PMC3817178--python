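"""Uncertainty-weighted Bayesian non-negative matrix factorization.

Decomposes a stacked data matrix ``D`` ((n_E + n_M) genes x m samples) with
per-element uncertainties ``Sigma`` into non-negative amplitudes ``A``
(rows x p) and patterns ``P`` (p x m) under the Gaussian likelihood

    L(A, P) ~ exp(-chi2(A, P) / 2),
    chi2 = sum_ij ((D_ij - (A P)_ij) / Sigma_ij)^2

with independent exponential (sparsity-inducing) priors on every element of
A and P.  Inference is by Markov chain Monte Carlo: each element has a
truncated-normal full conditional, so the chain is an exact Gibbs sampler.
Elements within one column of A (or one row of P) are conditionally
independent given the rest of the factorization, which lets each sweep be
performed as 2p vectorized block updates.

Posterior means and standard deviations of A and P are accumulated over the
post-burn-in sweeps.  All randomness flows through one
``numpy.random.Generator`` seeded per run, so identical seeds give
bit-identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .preprocess import CombinedDataset

__all__ = [
    "PriorConfig",
    "FactorizationResult",
    "RobustnessReport",
    "chi_squared",
    "factorize",
    "match_patterns",
    "greedy_match",
]


@dataclass(frozen=True)
class PriorConfig:
    """Exponential prior rates for amplitudes and patterns.

    Larger rates shrink elements harder toward zero (sparser solutions).
    """

    lambda_A: float = 1.0
    lambda_P: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_A <= 0 or self.lambda_P <= 0:
            raise ValueError("prior rates must be positive")


@dataclass
class FactorizationResult:
    """Posterior summaries of one MCMC NMF run."""

    A_mean: np.ndarray
    A_sd: np.ndarray
    P_mean: np.ndarray
    P_sd: np.ndarray
    chi2_trace: np.ndarray
    p: int
    seed: int
    n_burn: int
    n_sample: int

    def __post_init__(self) -> None:
        if np.any(self.A_mean < 0) or np.any(self.P_mean < 0):
            raise ValueError("posterior means must be non-negative")
        if np.any(self.A_sd < 0) or np.any(self.P_sd < 0):
            raise ValueError("posterior sds must be non-negative")
        if not np.all(np.isfinite(self.chi2_trace)):
            raise ValueError("chi2 trace contains non-finite values")


def chi_squared(
    D: np.ndarray, Sigma: np.ndarray, A: np.ndarray, P: np.ndarray
) -> float:
    """Uncertainty-weighted sum of squared residuals of the fit A @ P to D."""
    D = np.asarray(D, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if np.any(Sigma <= 0):
        raise ValueError("all uncertainties must be strictly positive")
    R = (D - np.asarray(A) @ np.asarray(P)) / Sigma
    return float(np.sum(R * R))


def _sample_lower_truncnorm(
    rng: np.random.Generator, mu: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Draw from N(mu, sigma^2) truncated to [0, inf), vectorized.

    Uses the inverse-CDF method expressed through the upper tail
    (x = mu - sigma * ndtri(u * Phi(mu/sigma))), which stays accurate for
    truncation points deep in the tail.  Where the tail mass underflows,
    falls back to the asymptotic exponential approximation of the tail.
    """
    alpha = -mu / sigma  # standardized lower bound
    tail = ndtr(-alpha)  # P(Z >= alpha)
    u = rng.random(mu.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = mu - sigma * ndtri(u * tail)
    # Deep-tail fallback: truncated normal at alpha >> 0 is ~ alpha + Exp(alpha)
    bad = ~np.isfinite(x) | (x < 0)
    if np.any(bad):
        a = np.maximum(alpha[bad], 1.0)
        x[bad] = mu[bad] + sigma[bad] * (alpha[bad] + rng.exponential(size=a.shape) / a)
        x[bad] = np.maximum(x[bad], 0.0)
    return x


def factorize(
    dataset: CombinedDataset | tuple[np.ndarray, np.ndarray],
    p: int,
    n_burn: int = 5000,
    n_sample: int = 5000,
    seed: int = 0,
    prior_config: PriorConfig | None = None,
    chi2_thin: int = 1,
) -> FactorizationResult:
    """Run the Gibbs sampler and return posterior summaries.

    Parameters
    ----------
    dataset
        A :class:`~metapathways.preprocess.CombinedDataset`, or a plain
        ``(D, Sigma)`` pair of equally shaped arrays.
    p
        Number of patterns; must satisfy ``1 <= p < min(n_rows, m)``.
    n_burn, n_sample
        Sweeps discarded, then sweeps averaged.  One sweep updates every
        element of A and P once.
    seed
        Seeds the run's generator; also used to initialize A, P from the
        prior.
    chi2_thin
        Record the chi-squared misfit every this many sweeps.
    """
    if isinstance(dataset, CombinedDataset):
        D, Sigma = dataset.D, dataset.Sigma
    else:
        D, Sigma = dataset
    D = np.ascontiguousarray(D, dtype=float)
    Sigma = np.ascontiguousarray(Sigma, dtype=float)
    if D.shape != Sigma.shape:
        raise ValueError("D and Sigma must have identical shapes")
    if not (np.all(np.isfinite(D)) and np.all(np.isfinite(Sigma))):
        raise ValueError("D and Sigma must be finite")
    if np.any(Sigma <= 0):
        raise ValueError("all uncertainties must be strictly positive")
    n, m = D.shape
    if not 1 <= p < min(n, m):
        raise ValueError(f"p={p} out of range [1, {min(n, m) - 1}]")
    if n_burn < 1 or n_sample < 1:
        raise ValueError("n_burn and n_sample must be >= 1")
    prior = prior_config or PriorConfig()

    rng = np.random.default_rng(seed)
    W = 1.0 / (Sigma * Sigma)  # precision weights
    A = rng.exponential(1.0 / prior.lambda_A, size=(n, p))
    P = rng.exponential(1.0 / prior.lambda_P, size=(p, m))
    AP = A @ P

    n_chi2 = (n_burn + n_sample + chi2_thin - 1) // chi2_thin
    chi2_trace = np.empty(n_chi2)
    A_sum = np.zeros_like(A)
    A_sq = np.zeros_like(A)
    P_sum = np.zeros_like(P)
    P_sq = np.zeros_like(P)

    for sweep in range(n_burn + n_sample):
        for k in range(p):
            # --- update column A[:, k] ---
            Pk = P[k]
            Rk = D - AP + np.outer(A[:, k], Pk)  # residual without component k
            tau = W @ (Pk * Pk)  # per-row precision
            b = (W * Rk) @ Pk  # per-row weighted projection
            free = tau <= 0.0
            tau_safe = np.where(free, 1.0, tau)
            mu = (b - prior.lambda_A) / tau_safe
            sig = 1.0 / np.sqrt(tau_safe)
            new_col = _sample_lower_truncnorm(rng, mu, sig)
            if np.any(free):  # pattern row is all zero: conditional = prior
                new_col[free] = rng.exponential(1.0 / prior.lambda_A, size=int(free.sum()))
            AP += np.outer(new_col - A[:, k], Pk)
            A[:, k] = new_col

            # --- update row P[k, :] ---
            Ak = A[:, k]
            Rk = D - AP + np.outer(Ak, P[k])
            tau = (Ak * Ak) @ W
            b = Ak @ (W * Rk)
            free = tau <= 0.0
            tau_safe = np.where(free, 1.0, tau)
            mu = (b - prior.lambda_P) / tau_safe
            sig = 1.0 / np.sqrt(tau_safe)
            new_row = _sample_lower_truncnorm(rng, mu, sig)
            if np.any(free):
                new_row[free] = rng.exponential(1.0 / prior.lambda_P, size=int(free.sum()))
            AP += np.outer(Ak, new_row - P[k])
            P[k] = new_row

        if sweep % chi2_thin == 0:
            R = (D - AP) * np.sqrt(W)
            chi2_trace[sweep // chi2_thin] = np.sum(R * R)
        if sweep >= n_burn:
            A_sum += A
            A_sq += A * A
            P_sum += P
            P_sq += P * P

    A_mean = A_sum / n_sample
    P_mean = P_sum / n_sample
    A_var = np.maximum(A_sq / n_sample - A_mean * A_mean, 0.0)
    P_var = np.maximum(P_sq / n_sample - P_mean * P_mean, 0.0)
    return FactorizationResult(
        A_mean=A_mean,
        A_sd=np.sqrt(A_var),
        P_mean=P_mean,
        P_sd=np.sqrt(P_var),
        chi2_trace=chi2_trace,
        p=p,
        seed=seed,
        n_burn=n_burn,
        n_sample=n_sample,
    )


def _pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between rows of X and rows of Y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    nx = np.sqrt(np.sum(Xc * Xc, axis=1))
    ny = np.sqrt(np.sum(Yc * Yc, axis=1))
    denom = np.outer(nx, ny)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (Xc @ Yc.T) / denom
    return np.where(denom > 0, C, 0.0)


def greedy_match(P1: np.ndarray, P2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match rows of P1 to rows of P2 by maximum Pearson correlation.

    Greedy without replacement: repeatedly take the globally best remaining
    pair.  Returns ``(assignment, correlations)`` where ``assignment[i]`` is
    the row of P2 matched to row i of P1.
    """
    C = _pearson_rows(np.asarray(P1, float), np.asarray(P2, float))
    p = C.shape[0]
    assignment = np.full(p, -1, dtype=int)
    corrs = np.full(p, np.nan)
    work = C.copy()
    for _ in range(p):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        assignment[i] = j
        corrs[i] = C[i, j]
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return assignment, corrs


@dataclass
class RobustnessReport:
    """Cross-seed pattern reproducibility for each number of patterns p.

    ``min_match_corr[p]`` holds, for each pattern of the first run at that
    p, the smallest best-match correlation over all pairs of runs; a pattern
    is robust when that minimum is at least the threshold.
    """

    threshold: float
    min_match_corr: dict[int, np.ndarray] = field(default_factory=dict)

    def robust_patterns(self, p: int) -> list[int]:
        return [int(k) for k, c in enumerate(self.min_match_corr[p]) if c >= self.threshold]

    def persistent(self, p: int) -> bool:
        """True when every pattern at this p reproduces across all seed pairs."""
        return len(self.robust_patterns(p)) == p


def match_patterns(
    results: Sequence[FactorizationResult], threshold: float = 0.8
) -> RobustnessReport:
    """Assess pattern robustness across replicate runs (and across p).

    Runs are grouped by their number of patterns p; within each group every
    pair of runs is matched greedily by Pearson correlation of P_mean rows.
    A pattern (indexed by the first run of the group) is robust when its
    match correlation reaches ``threshold`` in every pair involving run 0.
    """
    if len(results) < 2:
        raise ValueError("robustness needs replicates (>= 2 results)")
    report = RobustnessReport(threshold=threshold)
    by_p: dict[int, list[FactorizationResult]] = {}
    for r in results:
        by_p.setdefault(r.p, []).append(r)
    for p, group in sorted(by_p.items()):
        if len(group) < 2:
            warnings.warn(f"p={p} has a single run; skipped in robustness report")
            continue
        ref = group[0].P_mean
        mins = np.full(p, np.inf)
        for other in group[1:]:
            _, corrs = greedy_match(ref, other.P_mean)
            mins = np.minimum(mins, corrs)
        report.min_match_corr[p] = mins
    if not report.min_match_corr:
        raise ValueError("robustness needs replicates at a common p")
    return report
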