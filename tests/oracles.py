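"""Independent brute-force oracles used to check closed-form implementations.

These deliberately avoid the package's own likelihood code paths: the removal
likelihood oracle sums over the latent abundance explicitly, and the minimum
set oracle enumerates subsets exhaustively.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln


def brute_force_neg_loglik(lam_a: float, p: float, y, k_max: int = 500) -> float:
    """Removal-model negative log-likelihood for one site by explicit
    summation over the latent abundance N.

    Sums Poisson(N; λA) × Multinomial(y_1..y_J, N−T missed; π_1..π_J, π_miss)
    for N = T .. k_max, with π_j = p(1−p)^{j−1} and π_miss = (1−p)^J.
    """
    y = np.asarray(y, dtype=int)
    j_intervals = y.size
    total = int(y.sum())
    pi = np.array([p * (1 - p) ** j for j in range(j_intervals)])
    miss = (1 - p) ** j_intervals
    with np.errstate(divide="ignore", invalid="ignore"):
        log_obs = float(np.where(y > 0, y * np.log(pi), 0.0).sum())
    n_latent = np.arange(total, k_max)
    n_miss = n_latent - total
    log_pois = n_latent * np.log(lam_a) - lam_a - gammaln(n_latent + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        miss_term = np.where(n_miss > 0, n_miss * np.log(miss), 0.0)
    log_multi = (
        gammaln(n_latent + 1)
        - gammaln(y + 1).sum()
        - gammaln(n_miss + 1)
        + log_obs
        + miss_term
    )
    lik = float(np.exp(log_pois + log_multi).sum())
    return -float(np.log(lik))


def exhaustive_minimum_set_size(values: np.ndarray, target_frac: float) -> int:
    """Smallest subset of cells whose sum reaches target_frac of the total,
    found by exhaustive enumeration over subset sizes."""
    values = np.asarray(values, dtype=float).ravel()
    target = target_frac * values.sum()
    for size in range(1, values.size + 1):
        for combo in itertools.combinations(range(values.size), size):
            if values[list(combo)].sum() >= target * (1 - 1e-12):
                return size
    return values.size
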