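"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (full path enumeration, closed-form
textbook decompositions) and shares no code with the package internals.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.stats import norm


def _log_emissions(params, obs):
    """(T, K) per-observation log-densities, computed the naive way."""
    return np.stack(
        [
            norm.logpdf(obs, params.means[s], np.sqrt(params.variances[s])).sum(axis=1)
            for s in range(params.n_states)
        ],
        axis=1,
    )


def path_log_prob(params, obs, path) -> float:
    """Joint log-probability of one hidden path and the observations."""
    lb = _log_emissions(params, obs)
    lp = np.log(params.startprob[path[0]]) + lb[0, path[0]]
    for t in range(1, len(path)):
        lp += np.log(params.transmat[path[t - 1], path[t]]) + lb[t, path[t]]
    return float(lp)


def _enumerate_segment(params, seg):
    """All (path, log-prob) pairs for one segment."""
    k = params.n_states
    lb = _log_emissions(params, seg)
    log_pi = np.log(params.startprob)
    log_a = np.log(params.transmat)
    out = []
    for path in product(range(k), repeat=seg.shape[0]):
        lp = log_pi[path[0]] + lb[0, path[0]]
        for t in range(1, len(path)):
            lp += log_a[path[t - 1], path[t]] + lb[t, path[t]]
        out.append((path, lp))
    return out


def enumerate_forward_backward(params, obs, bounds):
    """Posteriors and log-likelihood by summing over every hidden path."""
    k = params.n_states
    total_ll = 0.0
    gammas = []
    for start, length in bounds:
        pairs = _enumerate_segment(params, obs[start : start + length])
        lls = np.array([lp for _, lp in pairs])
        m = lls.max()
        log_z = m + np.log(np.exp(lls - m).sum())
        total_ll += log_z
        gamma = np.zeros((length, k))
        for path, lp in pairs:
            w = np.exp(lp - log_z)
            for t, s in enumerate(path):
                gamma[t, s] += w
        gammas.append(gamma)
    return np.vstack(gammas), total_ll


def enumerate_viterbi_logprob(params, obs, bounds) -> float:
    """Max path log-probability by enumeration (value, not the path)."""
    return sum(
        max(lp for _, lp in _enumerate_segment(params, obs[start : start + length]))
        for start, length in bounds
    )


def random_instance(rng, t_max=6, k_max=3, c_max=2, n_segments=1):
    """A random small HMM instance plus observations and boundaries."""
    k = int(rng.integers(1, k_max + 1))
    c = int(rng.integers(1, c_max + 1))
    lengths = [int(rng.integers(1, t_max + 1)) for _ in range(n_segments)]
    if lengths[0] < 2:
        lengths[0] = 2
    bounds, start = [], 0
    for length in lengths:
        bounds.append((start, length))
        start += length
    from statedyn.hmm import HMMParams

    params = HMMParams(
        startprob=rng.dirichlet(np.ones(k)),
        transmat=rng.dirichlet(np.ones(k), size=k),
        means=rng.normal(size=(k, c)),
        variances=rng.uniform(0.5, 2.0, size=(k, c)),
    )
    obs = rng.normal(size=(start, c))
    return params, obs, bounds


def balanced_anova_ss(values: np.ndarray):
    """Classic balanced 2x2 decomposition from cell means.

    ``values`` has shape (2, 2, n): first axis factor A, second factor B.
    Returns (ss_a, ss_b, ss_ab, ss_error).
    """
    n = values.shape[2]
    grand = values.mean()
    a_means = values.mean(axis=(1, 2))
    b_means = values.mean(axis=(0, 2))
    cell_means = values.mean(axis=2)
    ss_a = 2 * n * ((a_means - grand) ** 2).sum()
    ss_b = 2 * n * ((b_means - grand) ** 2).sum()
    ss_cells = n * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_error = ((values - cell_means[:, :, None]) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_error
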