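"""State-switching metrics on decoded state sequences.

Per run: fractional occupancy (FO), empirical transition counts/probabilities,
dwell episodes, inter-transition interval (ITI) statistics, number of
transitions per time point (NT), and pooled 3-SD outlier screening.

States are 0-based internally and reported 1..K externally. The default ITI
convention counts a dwell of length L as L-1 (time points spent in a state
beyond the first), which is the convention consistent with an on-diagonal
transition probability p giving mean ITI 1/(1-p) - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .hmm import HMMParams, posterior_argmax, viterbi
from .io_cohort import TimeSeriesRun

ITI_CONVENTIONS = ("dwell", "dwell_minus_one")
DECODERS = ("viterbi", "posterior_argmax")


@dataclass
class StateSequence:
    """Decoded state label per time point for one run (0-based labels)."""

    run_id: str
    labels: np.ndarray
    decoder: str = "viterbi"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValidationError(f"run {self.run_id}: labels must be a non-empty vector")
        if self.labels.min() < 0:
            raise ValidationError(f"run {self.run_id}: negative state label")

    @property
    def n_timepoints(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class DwellEpisode:
    state: int
    length: int
    start_index: int


@dataclass
class TransitionCounts:
    counts: np.ndarray  # (K, K) ints
    tpm: np.ndarray  # (K, K); rows with no outgoing transitions are NaN
    undefined_rows: np.ndarray  # bool mask of NaN rows


@dataclass
class DynamicsRecord:
    """All switching metrics for one run."""

    run_id: str
    fo: np.ndarray
    nt: float
    iti_mean: float
    iti_sd: float | None
    per_state_iti: dict[int, float]
    per_state_iti_sd: dict[int, float] = field(default_factory=dict)
    outlier_iti: bool = False
    outlier_nt: bool = False


def decode_run(
    group_params: HMMParams,
    relabeling: np.ndarray | None,
    run: TimeSeriesRun,
    decoder: str = "viterbi",
) -> StateSequence:
    """Decode one run with its group's model, in consensus label space.

    The run must already be z-scored with the fitting convention.
    ``relabeling[local_state] = consensus_label``; pass None to keep local
    labels.
    """
    if decoder not in DECODERS:
        raise ValidationError(f"unknown decoder {decoder!r}")
    if run.n_channels != group_params.n_channels:
        raise ValidationError(
            f"run {run.run_id} has {run.n_channels} channels, "
            f"model has {group_params.n_channels}"
        )
    decode = viterbi if decoder == "viterbi" else posterior_argmax
    local = decode(group_params, run.data, [(0, run.n_timepoints)])
    labels = local if relabeling is None else np.asarray(relabeling, dtype=int)[local]
    return StateSequence(run_id=run.run_id, labels=labels, decoder=decoder)


def fractional_occupancy(
    seqs: list[StateSequence] | StateSequence, k: int, level: str = "run"
) -> np.ndarray:
    """Proportion of time points per state.

    ``level='run'`` returns one K-simplex per sequence (n_runs x K);
    ``level='group'`` pools all time points first and returns one K-vector.
    """
    if isinstance(seqs, StateSequence):
        seqs = [seqs]
    if not seqs:
        raise DegenerateInputError("fractional occupancy of an empty sequence list")
    if level not in ("run", "group"):
        raise ValidationError(f"unknown level {level!r}")
    counts = np.stack(
        [np.bincount(s.labels, minlength=k).astype(float) for s in seqs]
    )
    if np.any(counts.sum(axis=1) == 0):
        raise DegenerateInputError("empty state sequence")
    if level == "group":
        pooled = counts.sum(axis=0)
        return pooled / pooled.sum()
    return counts / counts.sum(axis=1, keepdims=True)


def empirical_transitions(seq: StateSequence, k: int) -> TransitionCounts:
    """Count s_t -> s_{t+1} pairs; rows without outgoing mass are NaN."""
    labels = seq.labels
    if labels.size < 2:
        raise DegenerateInputError(f"run {seq.run_id}: need T >= 2 for transitions")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (labels[:-1], labels[1:]), 1)
    row_sums = counts.sum(axis=1)
    undefined = row_sums == 0
    tpm = np.full((k, k), np.nan)
    tpm[~undefined] = counts[~undefined] / row_sums[~undefined, None]
    return TransitionCounts(counts=counts, tpm=tpm, undefined_rows=undefined)


def dwell_episodes(seq: StateSequence) -> list[DwellEpisode]:
    """Maximal constant runs, in order; the final (censored) episode included."""
    labels = seq.labels
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return [
        DwellEpisode(state=int(labels[s]), length=int(e - s), start_index=int(s))
        for s, e in zip(starts, ends)
    ]


def iti_stats(
    episodes: list[DwellEpisode], k: int, convention: str = "dwell_minus_one"
) -> tuple[float, float | None, dict[int, float], dict[int, float]]:
    """Run-level and per-state ITI mean/SD over dwell episodes.

    Returns (iti_mean, iti_sd, per_state_mean, per_state_sd); SDs are sample
    SDs and None/missing when fewer than 2 episodes exist. Unvisited states
    are missing from the per-state dicts, not zero.
    """
    if convention not in ITI_CONVENTIONS:
        raise ValidationError(f"unknown ITI convention {convention!r}")
    if not episodes:
        raise DegenerateInputError("no dwell episodes")
    offset = 0 if convention == "dwell" else 1
    values = np.array([e.length - offset for e in episodes], dtype=float)
    iti_mean = float(values.mean())
    iti_sd = float(values.std(ddof=1)) if values.size >= 2 else None
    per_state: dict[int, float] = {}
    per_state_sd: dict[int, float] = {}
    states = np.array([e.state for e in episodes])
    for s in range(k):
        vals = values[states == s]
        if vals.size:
            per_state[s] = float(vals.mean())
            if vals.size >= 2:
                per_state_sd[s] = float(vals.std(ddof=1))
    return iti_mean, iti_sd, per_state, per_state_sd


def number_of_transitions(seq: StateSequence) -> float:
    """State changes divided by the run length (transitions per time point)."""
    labels = seq.labels
    if labels.size < 2:
        raise DegenerateInputError(f"run {seq.run_id}: need T >= 2 for NT")
    return float(np.count_nonzero(np.diff(labels) != 0)) / labels.size


@dataclass
class OutlierReport:
    removed: list[tuple[str, float]]  # (run_id, z)
    zero_variance: bool = False


def screen_outliers(
    values: np.ndarray,
    run_ids: list[str] | None = None,
    threshold_sd: float = 3.0,
) -> tuple[np.ndarray, OutlierReport]:
    """Single-pass pooled z-score screening: drop runs with |z| > threshold.

    Scaling uses mean and sample SD over ALL provided values (pooled across
    groups); |z| exactly equal to the threshold is retained. Returns a keep
    mask and a report of removed runs.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise DegenerateInputError("outlier screening needs at least 3 values")
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite metric values in outlier screening")
    if run_ids is None:
        run_ids = [str(i) for i in range(values.size)]
    sd = values.std(ddof=1)
    if sd == 0.0:
        warnings.warn("outlier screening: zero variance, nothing removed", stacklevel=2)
        return np.ones(values.size, dtype=bool), OutlierReport([], zero_variance=True)
    z = (values - values.mean()) / sd
    keep = np.abs(z) <= threshold_sd
    removed = [(run_ids[i], float(z[i])) for i in np.flatnonzero(~keep)]
    return keep, OutlierReport(removed)


def compute_record(
    seq: StateSequence, k: int, convention: str = "dwell_minus_one"
) -> DynamicsRecord:
    """Bundle all per-run metrics for one decoded sequence."""
    fo = fractional_occupancy(seq, k, level="run")[0]
    episodes = dwell_episodes(seq)
    iti_mean, iti_sd, per_state, per_state_sd = iti_stats(episodes, k, convention)
    nt = number_of_transitions(seq)
    return DynamicsRecord(
        run_id=seq.run_id,
        fo=fo,
        nt=nt,
        iti_mean=iti_mean,
        iti_sd=iti_sd,
        per_state_iti=per_state,
        per_state_iti_sd=per_state_sd,
    )


def records_to_frame(
    records: list[DynamicsRecord], k: int, groups: dict[str, tuple[str, str]]
) -> pd.DataFrame:
    """Tabulate records (one row per run, states reported 1..K)."""
    rows = []
    for rec in records:
        sex, dx = groups[rec.run_id]
        row: dict[str, object] = {
            "run_id": rec.run_id,
            "sex": sex,
            "dx": dx,
            "nt": rec.nt,
            "iti_mean": rec.iti_mean,
            "iti_sd": np.nan if rec.iti_sd is None else rec.iti_sd,
            "outlier_iti": rec.outlier_iti,
            "outlier_nt": rec.outlier_nt,
        }
        for s in range(k):
            row[f"fo_{s + 1}"] = rec.fo[s]
            row[f"iti_state_{s + 1}"] = rec.per_state_iti.get(s, np.nan)
            row[f"iti_sd_state_{s + 1}"] = rec.per_state_iti_sd.get(s, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def apply_outlier_flags(
    df: pd.DataFrame, threshold_sd: float = 3.0
) -> tuple[pd.DataFrame, dict[str, OutlierReport]]:
    """Screen the ITI family (mean and SD jointly) and NT separately.

    A run is an ITI-family outlier if either its ITI mean or ITI SD exceeds
    the pooled threshold; NT is screened on its own. Flags are added in
    place-like fashion on a copy.
    """
    out = df.copy()
    ids = out["run_id"].tolist()
    reports: dict[str, OutlierReport] = {}
    keep_mean, reports["iti_mean"] = screen_outliers(
        out["iti_mean"].to_numpy(), ids, threshold_sd
    )
    sd_vals = out["iti_sd"].to_numpy()
    finite_sd = np.isfinite(sd_vals)
    keep_sd = np.ones(len(out), dtype=bool)
    if finite_sd.sum() >= 3:
        keep_sub, rep = screen_outliers(
            sd_vals[finite_sd], [ids[i] for i in np.flatnonzero(finite_sd)], threshold_sd
        )
        keep_sd[np.flatnonzero(finite_sd)] = keep_sub
        reports["iti_sd"] = rep
    keep_nt, reports["nt"] = screen_outliers(out["nt"].to_numpy(), ids, threshold_sd)
    out["outlier_iti"] = ~(keep_mean & keep_sd)
    out["outlier_nt"] = ~keep_nt
    return out, reports
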