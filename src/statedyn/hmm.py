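"""Gaussian-emission hidden Markov model: exact inference, EM, model-order scan.

Inference uses the scaled forward-backward recursions, batched across run
segments (the chain is broken at every run boundary: transitions across
concatenated scans are physically meaningless). Per-step emission densities
are rescaled by their row maximum before exponentiation so long channels
cannot underflow.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg as sla
from sklearn.cluster import KMeans

from .errors import DegenerateInputError, NumericalError, ValidationError
from .seeding import derive_seed

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-6
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HMMParams:
    """Parameters of a K-state Gaussian-emission HMM over C channels."""

    startprob: np.ndarray  # (K,)
    transmat: np.ndarray  # (K, K) row-stochastic
    means: np.ndarray  # (K, C)
    variances: np.ndarray  # (K, C) diagonal or (K, C, C) full
    covariance: str = "diagonal"

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.asarray(self.variances, dtype=float)
        k = self.startprob.shape[0]
        if self.transmat.shape != (k, k):
            raise ValidationError("transition matrix shape does not match startprob")
        if abs(self.startprob.sum() - 1.0) > 1e-12:
            raise ValidationError("initial probabilities must sum to 1")
        if np.any(np.abs(self.transmat.sum(axis=1) - 1.0) > 1e-12):
            raise ValidationError("every transition-matrix row must sum to 1")
        if self.covariance not in ("diagonal", "full"):
            raise ValidationError(f"unknown covariance kind {self.covariance!r}")
        if self.covariance == "diagonal":
            if self.variances.shape != self.means.shape:
                raise ValidationError("diagonal variances must be K x C")
            if np.any(self.variances < VAR_FLOOR - 1e-15):
                raise ValidationError(f"variances below floor {VAR_FLOOR}")
        else:
            kk, c = self.means.shape
            if self.variances.shape != (kk, c, c):
                raise ValidationError("full covariances must be K x C x C")

    @property
    def n_states(self) -> int:
        return self.startprob.shape[0]

    @property
    def n_channels(self) -> int:
        return self.means.shape[1]

    def to_dict(self) -> dict:
        return {
            "covariance": self.covariance,
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            startprob=np.array(d["startprob"]),
            transmat=np.array(d["transmat"]),
            means=np.array(d["means"]),
            variances=np.array(d["variances"]),
            covariance=d.get("covariance", "diagonal"),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "HMMParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ScanEntry:
    k: int
    log_likelihood: float
    params: HMMParams | None
    n_iterations: int
    converged: bool


@dataclass
class FitScan:
    """Per-K fit results of :func:`scan_states` (K strictly increasing)."""

    entries: list[ScanEntry] = field(default_factory=list)

    def k_values(self) -> list[int]:
        return [e.k for e in self.entries]

    def log_likelihoods(self) -> np.ndarray:
        return np.array([e.log_likelihood for e in self.entries])


@dataclass
class ElbowResult:
    selected_k: int
    k_values: list[int]
    deltas: np.ndarray  # improvement L(K) - L(K-1), NaN for first entry
    second_diffs: np.ndarray  # NaN for the two boundary entries
    no_clear_elbow: bool = False


# ---------------------------------------------------------------------------
# emission log-densities


def log_emission_matrix(params: HMMParams, obs: np.ndarray) -> np.ndarray:
    """(T, K) log-density of each observation under each state."""
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    k, c = params.means.shape
    if obs.shape[1] != c:
        raise ValidationError(f"observations have {obs.shape[1]} channels, model has {c}")
    if params.covariance == "diagonal":
        var = params.variances
        if np.any(var <= 0):
            s, ch = np.unravel_index(int(np.argmin(var)), var.shape)
            raise NumericalError(f"non-positive variance at state {s}, channel {ch}")
        prec = 1.0 / var
        const = -0.5 * (c * _LOG2PI + np.log(var).sum(axis=1))
        quad = (
            (obs**2) @ prec.T
            - 2.0 * obs @ (params.means * prec).T
            + ((params.means**2) * prec).sum(axis=1)
        )
        out = const - 0.5 * quad
    else:
        out = np.empty((obs.shape[0], k))
        for s in range(k):
            cov = params.variances[s]
            try:
                cho = sla.cho_factor(cov, lower=True)
            except sla.LinAlgError as exc:
                raise NumericalError(f"covariance of state {s} not SPD") from exc
            diff = obs - params.means[s]
            solved = sla.cho_solve(cho, diff.T).T
            logdet = 2.0 * np.log(np.diag(cho[0])).sum()
            out[:, s] = -0.5 * (c * _LOG2PI + logdet + np.einsum("tc,tc->t", diff, solved))
    if not np.all(np.isfinite(out)):
        t, s = np.unravel_index(int(np.argmin(np.isfinite(out))), out.shape)
        raise NumericalError(f"non-finite log-density at time {t}, state {s}")
    return out


# ---------------------------------------------------------------------------
# batched scaled forward-backward


def _normalize_boundaries(t_total: int, boundaries) -> list[tuple[int, int]]:
    if boundaries is None:
        return [(0, t_total)]
    bounds = [(int(s), int(length)) for s, length in boundaries]
    bounds.sort()
    pos = 0
    for s, length in bounds:
        if s != pos or length < 1:
            raise ValidationError("boundaries must partition the observation rows")
        pos += length
    if pos != t_total:
        raise ValidationError(
            f"boundaries cover {pos} rows but observations have {t_total}"
        )
    return bounds


def _pad_segments(values: np.ndarray, bounds: list[tuple[int, int]]):
    """Stack variable-length segments into (S, Tmax, K), longest first."""
    lengths = np.array([length for _, length in bounds])
    order = np.argsort(-lengths, kind="stable")
    t_max = int(lengths.max())
    k = values.shape[1]
    padded = np.zeros((len(bounds), t_max, k))
    for slot, seg in enumerate(order):
        start, length = bounds[seg]
        padded[slot, :length] = values[start : start + length]
    return padded, lengths[order], order


def _batched_forward_backward(
    params: HMMParams, log_b: np.ndarray, bounds: list[tuple[int, int]]
):
    """Scaled forward-backward over padded segments.

    Returns (gamma, xi_sum, start_counts, loglik) where gamma is in original
    row order, xi_sum is the (K, K) expected transition-count matrix summed
    over all segments, and start_counts is the summed posterior at segment
    starts.
    """
    a = params.transmat
    pi = params.startprob
    k = params.n_states
    padded_log_b, lengths, order = _pad_segments(log_b, bounds)
    s_count, t_max, _ = padded_log_b.shape

    b_max = padded_log_b.max(axis=2)
    b_scaled = np.exp(padded_log_b - b_max[:, :, None])

    alpha = np.zeros((s_count, t_max, k))
    c_norm = np.zeros((s_count, t_max))
    a0 = pi[None, :] * b_scaled[:, 0]
    c_norm[:, 0] = a0.sum(axis=1)
    alpha[:, 0] = a0 / c_norm[:, 0][:, None]
    # lengths are sorted descending so active segments form a prefix:
    # alpha at step t exists for segments with length > t
    for t in range(1, t_max):
        m = int(np.searchsorted(-lengths, -t, side="left"))
        if m == 0:
            break
        at = (alpha[:m, t - 1] @ a) * b_scaled[:m, t]
        tot = at.sum(axis=1)
        if np.any(tot <= 0):
            raise NumericalError(f"forward pass underflowed at step {t}")
        c_norm[:m, t] = tot
        alpha[:m, t] = at / tot[:, None]

    beta = np.zeros((s_count, t_max, k))
    xi_sum = np.zeros((k, k))
    for t in range(t_max - 1, -1, -1):
        ending = lengths - 1 == t
        if np.any(ending):
            beta[ending, t] = 1.0
        # beta update at t needs step t+1, i.e. segments with length >= t+2
        m = int(np.searchsorted(-lengths, -(t + 1), side="left"))
        if m > 0:
            w = b_scaled[:m, t + 1] * beta[:m, t + 1] / c_norm[:m, t + 1][:, None]
            beta[:m, t] = w @ a.T
            xi_sum += np.einsum("sk,sl->kl", alpha[:m, t], w) * a

    gamma_padded = alpha * beta
    start_counts = gamma_padded[:, 0].sum(axis=0)

    gamma = np.empty_like(log_b)
    loglik = 0.0
    for slot, seg in enumerate(order):
        start, length = bounds[seg]
        gamma[start : start + length] = gamma_padded[slot, :length]
        loglik += float(np.log(c_norm[slot, :length]).sum() + b_max[slot, :length].sum())
    return gamma, xi_sum, start_counts, loglik


def forward_backward(
    params: HMMParams, obs: np.ndarray, boundaries=None
) -> tuple[np.ndarray, float]:
    """Posterior state probabilities and total log-likelihood.

    The recursions restart at every run boundary; the log-likelihood is the
    sum over runs. Posterior rows sum to 1.
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    if not np.all(np.isfinite(obs)):
        raise ValidationError("observations contain non-finite values")
    bounds = _normalize_boundaries(obs.shape[0], boundaries)
    log_b = log_emission_matrix(params, obs)
    gamma, _, _, loglik = _batched_forward_backward(params, log_b, bounds)
    return gamma, loglik


def viterbi(params: HMMParams, obs: np.ndarray, boundaries=None) -> np.ndarray:
    """Jointly most probable state path per run (0-based labels).

    Ties are broken toward the lower state index, deterministically.
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    bounds = _normalize_boundaries(obs.shape[0], boundaries)
    log_b = log_emission_matrix(params, obs)
    with np.errstate(divide="ignore"):
        log_a = np.log(params.transmat)
        log_pi = np.log(params.startprob)
    path = np.empty(obs.shape[0], dtype=int)
    for start, length in bounds:
        seg = log_b[start : start + length]
        delta = log_pi + seg[0]
        psi = np.empty((length, params.n_states), dtype=int)
        for t in range(1, length):
            scores = delta[:, None] + log_a
            psi[t] = np.argmax(scores, axis=0)  # argmax picks lowest index on ties
            delta = scores[psi[t], np.arange(params.n_states)] + seg[t]
        state = int(np.argmax(delta))
        seg_path = np.empty(length, dtype=int)
        seg_path[-1] = state
        for t in range(length - 1, 0, -1):
            state = int(psi[t, state])
            seg_path[t - 1] = state
        path[start : start + length] = seg_path
    return path


def posterior_argmax(params: HMMParams, obs: np.ndarray, boundaries=None) -> np.ndarray:
    """Per-time-point argmax of the state posterior (alternative decoder)."""
    gamma, _ = forward_backward(params, obs, boundaries)
    return np.argmax(gamma, axis=1)


# ---------------------------------------------------------------------------
# EM fitting


def _init_params(
    obs: np.ndarray, k: int, covariance: str, seed: int, on_diag: float = 0.5
) -> HMMParams:
    """K-means means, global variances, uniform pi, 0.5-sticky transitions."""
    t, c = obs.shape
    if k == 1:
        means = obs.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=1, random_state=seed % (2**32)).fit(obs)
        means = km.cluster_centers_
    global_var = np.maximum(obs.var(axis=0), VAR_FLOOR)
    if covariance == "diagonal":
        variances = np.tile(global_var, (k, 1))
    else:
        base = np.cov(obs.T, ddof=0) if c > 1 else np.array([[global_var[0]]])
        base = base + VAR_FLOOR * np.eye(c)
        variances = np.tile(base, (k, 1, 1))
    if k == 1:
        transmat = np.ones((1, 1))
    else:
        off = (1.0 - on_diag) / (k - 1)
        transmat = np.full((k, k), off)
        np.fill_diagonal(transmat, on_diag)
    return HMMParams(
        startprob=np.full(k, 1.0 / k),
        transmat=transmat,
        means=means,
        variances=variances,
        covariance=covariance,
    )


def _m_step(
    obs: np.ndarray,
    gamma: np.ndarray,
    xi_sum: np.ndarray,
    start_counts: np.ndarray,
    covariance: str,
    var_floor: float,
    log_b: np.ndarray,
) -> HMMParams:
    k = gamma.shape[1]
    nk = gamma.sum(axis=0)
    empty = np.flatnonzero(nk < 1e-8)
    if empty.size:
        # re-seed dead states at the observation the model explains worst
        total_density = log_b.max(axis=1)
        worst = np.argsort(total_density)
        for j, s in enumerate(empty):
            logger.warning("EM: state %d lost all posterior mass; re-seeding", s)
            gamma[worst[j], :] = 0.0
            gamma[worst[j], s] = 1.0
        nk = gamma.sum(axis=0)

    startprob = start_counts / start_counts.sum()
    row_sums = xi_sum.sum(axis=1, keepdims=True)
    transmat = np.where(row_sums > 0, xi_sum / np.where(row_sums > 0, row_sums, 1.0), 1.0 / k)
    transmat /= transmat.sum(axis=1, keepdims=True)

    means = (gamma.T @ obs) / nk[:, None]
    if covariance == "diagonal":
        ex2 = (gamma.T @ (obs**2)) / nk[:, None]
        variances = np.maximum(ex2 - means**2, var_floor)
        if empty.size:
            variances[empty] = np.maximum(obs.var(axis=0), var_floor)
    else:
        c = obs.shape[1]
        variances = np.empty((k, c, c))
        for s in range(k):
            diff = obs - means[s]
            variances[s] = (diff.T * gamma[:, s]) @ diff / nk[s] + var_floor * np.eye(c)
    return HMMParams(
        startprob=startprob,
        transmat=transmat,
        means=means,
        variances=variances,
        covariance=covariance,
    )


def em_fit(
    obs: np.ndarray,
    boundaries=None,
    k: int = 5,
    covariance: str = "diagonal",
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
    var_floor: float = VAR_FLOOR,
) -> tuple[HMMParams, np.ndarray]:
    """Maximum-likelihood EM fit; best of ``n_restarts`` by final log-likelihood.

    Convergence when the relative log-likelihood change drops below ``tol``.
    Returns the winning parameters and their log-likelihood trace.
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    t = obs.shape[0]
    if k < 1:
        raise ValidationError("K must be >= 1")
    if t <= k:
        raise DegenerateInputError(f"need T > K, got T={t}, K={k}")
    bounds = _normalize_boundaries(t, boundaries)

    best: tuple[float, HMMParams, np.ndarray] | None = None
    for restart in range(max(1, n_restarts)):
        params = _init_params(obs, k, covariance, derive_seed(seed, "init", restart))
        trace: list[float] = []
        prev = -np.inf
        for _ in range(max_iter):
            log_b = log_emission_matrix(params, obs)
            gamma, xi_sum, start_counts, loglik = _batched_forward_backward(
                params, log_b, bounds
            )
            trace.append(loglik)
            if loglik < prev - 1e-8 * (1.0 + abs(prev)):
                logger.warning(
                    "EM: log-likelihood decreased (%.6g -> %.6g)", prev, loglik
                )
            if np.isfinite(prev) and abs(loglik - prev) <= tol * (1.0 + abs(prev)):
                prev = loglik
                break
            prev = loglik
            params = _m_step(
                obs, gamma, xi_sum, start_counts, covariance, var_floor, log_b
            )
        if best is None or prev > best[0]:
            best = (prev, params, np.array(trace))
    assert best is not None
    return best[1], best[2]


def scan_states(
    obs: np.ndarray,
    boundaries=None,
    k_min: int = 1,
    k_max: int = 10,
    covariance: str = "diagonal",
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
) -> FitScan:
    """Fit one model per K in [k_min, k_max] with shared settings.

    Per-K seeds are derived from ``seed``. A K whose fit raises is recorded
    as missing (params=None) without aborting the scan.
    """
    if k_min < 1 or k_max < k_min:
        raise ValidationError(f"invalid scan range [{k_min}, {k_max}]")
    scan = FitScan()
    prev_ll = -np.inf
    for k in range(k_min, k_max + 1):
        try:
            params, trace = em_fit(
                obs,
                boundaries,
                k=k,
                covariance=covariance,
                n_restarts=n_restarts,
                max_iter=max_iter,
                tol=tol,
                seed=derive_seed(seed, "scan", k),
            )
        except Exception:  # noqa: BLE001 - a failed K must not kill the scan
            logger.exception("scan_states: fit failed for K=%d", k)
            scan.entries.append(ScanEntry(k, float("nan"), None, 0, False))
            continue
        ll = float(trace[-1])
        if ll < prev_ll:
            logger.warning(
                "scan_states: log-likelihood decreased from K=%d to K=%d "
                "(local optimum)", k - 1, k
            )
        prev_ll = ll
        converged = len(trace) < max_iter
        scan.entries.append(ScanEntry(k, ll, params, len(trace), converged))
    return scan


def select_elbow(scan: FitScan) -> ElbowResult:
    """Pick K at the largest second difference of the log-likelihood curve.

    ``dd(K) = [L(K) - L(K-1)] - [L(K+1) - L(K)]``, maximized over interior K;
    ties go to the smaller K. The full table is returned so the choice can be
    overridden manually.
    """
    entries = [e for e in scan.entries if e.params is not None]
    if len(entries) < 3:
        raise DegenerateInputError("elbow selection needs at least 3 scan entries")
    ks = [e.k for e in entries]
    ll = np.array([e.log_likelihood for e in entries])
    deltas = np.full(len(ks), np.nan)
    deltas[1:] = np.diff(ll)
    second = np.full(len(ks), np.nan)
    second[1:-1] = deltas[1:-1] - deltas[2:]
    interior = second[1:-1]
    no_elbow = bool(np.allclose(interior, 0.0, atol=1e-12))
    if no_elbow:
        logger.warning("select_elbow: no clear elbow (constant improvement)")
        best = 0
    else:
        best = int(np.argmax(interior))  # argmax -> smallest K on exact ties
    return ElbowResult(
        selected_k=ks[1 + best],
        k_values=ks,
        deltas=deltas,
        second_diffs=second,
        no_clear_elbow=no_elbow,
    )
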