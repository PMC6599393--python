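"""Synthetic multi-group cohorts from known ground-truth HMMs.

Each sex x diagnosis group gets its own transition matrix (configurable
on-diagonal mass, remainder split evenly off-diagonal) and emission means
(shared templates plus per-group jitter). Per-run transition matrices are
row-renormalized logit-space perturbations of the group matrix, so dwell
variability can be injected per group (e.g. larger for ADHD). Sex/diagnosis
effects on dwell dynamics are injected through those two knobs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .hmm import HMMParams, VAR_FLOOR
from .io_cohort import (
    GROUP_KEYS,
    SubjectRecord,
    TimeSeriesRun,
    write_phenotypes,
    write_roi_timeseries,
)
from .seeding import derive_rng

GroupKey = tuple[str, str]


def orthogonal_templates(
    k: int, c: int, separation: float, rng: np.random.Generator
) -> np.ndarray:
    """K orthogonal C-vectors with pairwise Euclidean distance ``separation``.

    With unit emission noise, ``separation`` is the between-state mean
    distance in noise-SD units.
    """
    if c < k:
        raise ValidationError(f"need C >= K for orthogonal templates (K={k}, C={c})")
    q, _ = np.linalg.qr(rng.standard_normal((c, k)))
    return q.T * (separation / np.sqrt(2.0))


def _as_per_group(value, name: str) -> dict[GroupKey, float]:
    """Broadcast a scalar or 4-sequence to a per-group dict in canonical order."""
    if np.isscalar(value):
        return {g: float(value) for g in GROUP_KEYS}
    vals = list(value)
    if len(vals) != len(GROUP_KEYS):
        raise ValidationError(f"{name} must be a scalar or {len(GROUP_KEYS)} values")
    return {g: float(v) for g, v in zip(GROUP_KEYS, vals)}


@dataclass
class GroundTruthConfig:
    """Knobs of the generative model; defaults give a null 5-state cohort."""

    n_states: int = 5
    n_channels: int = 20
    runs_per_group: tuple[int, int, int, int] = (10, 10, 10, 10)
    run_length_range: tuple[int, int] = (80, 230)
    on_diag_by_group: tuple[float, float, float, float] | float = 0.53
    state_map_templates: np.ndarray | None = None
    template_separation: float = 2.0
    map_group_jitter_sd: float = 0.05
    emission_noise_sd: float = 1.0
    subject_tpm_jitter_sd: tuple[float, float, float, float] | float = 0.0
    tpm_jitter_mode: str = "diagonal"
    seed: int = 0

    def validate(self) -> None:
        if self.n_states < 2:
            raise ValidationError("n_states must be >= 2")
        if self.run_length_range[0] < 10 or self.run_length_range[1] < self.run_length_range[0]:
            raise ValidationError("run_length_range must satisfy 10 <= Tmin <= Tmax")
        if any(n < 1 for n in self.runs_per_group):
            raise ValidationError("runs_per_group must all be >= 1")
        for g, p in _as_per_group(self.on_diag_by_group, "on_diag_by_group").items():
            if not 0.0 < p < 1.0:
                raise ValidationError(f"on-diagonal for group {g} must lie in (0, 1)")
        for g, s in _as_per_group(self.subject_tpm_jitter_sd, "subject_tpm_jitter_sd").items():
            if s < 0:
                raise ValidationError(f"tpm jitter for group {g} must be non-negative")
        if self.emission_noise_sd <= 0:
            raise ValidationError("emission_noise_sd must be positive")
        if self.tpm_jitter_mode not in ("diagonal", "row"):
            raise ValidationError(
                f"tpm_jitter_mode must be 'diagonal' or 'row', got {self.tpm_jitter_mode!r}"
            )
        if self.map_group_jitter_sd < 0:
            raise ValidationError("map_group_jitter_sd must be non-negative")
        if self.state_map_templates is not None:
            tpl = np.asarray(self.state_map_templates, dtype=float)
            if tpl.shape != (self.n_states, self.n_channels):
                raise ValidationError(
                    f"state_map_templates must be {self.n_states} x {self.n_channels}"
                )


@dataclass
class GroundTruthModel:
    """Frozen truth: per-group HMM parameters and per-run transition matrices."""

    config: GroundTruthConfig
    templates: np.ndarray
    group_params: dict[GroupKey, HMMParams]
    run_transmats: dict[GroupKey, list[np.ndarray]]
    seed: int

    def group_transmat(self, group_key: GroupKey) -> np.ndarray:
        return self.group_params[group_key].transmat


def sticky_transmat(k: int, on_diag: float) -> np.ndarray:
    """K x K matrix with ``on_diag`` on the diagonal, rest split evenly."""
    a = np.full((k, k), (1.0 - on_diag) / (k - 1))
    np.fill_diagonal(a, on_diag)
    return a


def stationary_distribution(a: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix."""
    k = a.shape[0]
    m = np.vstack([a.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(m, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _jitter_transmat(
    a: np.ndarray, sd: float, rng: np.random.Generator, mode: str = "diagonal"
) -> np.ndarray:
    """Row-renormalized logit-space perturbation of a transition matrix.

    ``diagonal`` perturbs only the self-transition logit (one draw per row),
    which moves each row's dwell tendency while keeping off-diagonal mass
    even - the cleanest dwell-variability knob. ``row`` perturbs every cell.
    """
    if sd == 0.0:
        return a.copy()
    z = np.log(a)
    if mode == "diagonal":
        z[np.diag_indices_from(z)] += rng.normal(0.0, sd, size=a.shape[0])
    elif mode == "row":
        z = z + rng.normal(0.0, sd, size=a.shape)
    else:
        raise ValidationError(f"unknown tpm jitter mode {mode!r}")
    out = np.exp(z - z.max(axis=1, keepdims=True))
    return out / out.sum(axis=1, keepdims=True)


def make_ground_truth(config: GroundTruthConfig) -> GroundTruthModel:
    """Materialize group-level and per-run parameters from a config."""
    config.validate()
    k, c = config.n_states, config.n_channels
    rng_templates = derive_rng(config.seed, "templates")
    if config.state_map_templates is not None:
        templates = np.asarray(config.state_map_templates, dtype=float).copy()
    else:
        templates = orthogonal_templates(k, c, config.template_separation, rng_templates)

    on_diag = _as_per_group(config.on_diag_by_group, "on_diag_by_group")
    tpm_jitter = _as_per_group(config.subject_tpm_jitter_sd, "subject_tpm_jitter_sd")
    group_params: dict[GroupKey, HMMParams] = {}
    run_transmats: dict[GroupKey, list[np.ndarray]] = {}
    for g_idx, g in enumerate(GROUP_KEYS):
        a = sticky_transmat(k, on_diag[g])
        rng_g = derive_rng(config.seed, "group", g_idx)
        means = templates + rng_g.normal(0.0, config.map_group_jitter_sd, size=(k, c))
        group_params[g] = HMMParams(
            startprob=stationary_distribution(a),
            transmat=a,
            means=means,
            variances=np.full((k, c), max(config.emission_noise_sd**2, VAR_FLOOR)),
        )
        run_transmats[g] = [
            _jitter_transmat(
                a, tpm_jitter[g], derive_rng(config.seed, "run_tpm", g_idx, r),
                mode=config.tpm_jitter_mode,
            )
            for r in range(config.runs_per_group[g_idx])
        ]
    return GroundTruthModel(
        config=config,
        templates=templates,
        group_params=group_params,
        run_transmats=run_transmats,
        seed=config.seed,
    )


def simulate_run(
    model: GroundTruthModel,
    group_key: GroupKey,
    run_index: int,
    t: int,
    rng: np.random.Generator,
    subject_id: str = "sim",
    run_id: str = "sim_run",
) -> tuple[TimeSeriesRun, np.ndarray]:
    """Sample one run: hidden Markov path plus Gaussian observations.

    The initial state is drawn from the stationary distribution of the run's
    own transition matrix. Returns the run and the true 0-based path.
    """
    if t < 2:
        raise ValidationError(f"run length T={t} < 2")
    a = model.run_transmats[group_key][run_index]
    k = a.shape[0]
    cum = np.cumsum(a, axis=1)
    pi = stationary_distribution(a)
    path = np.empty(t, dtype=int)
    path[0] = rng.choice(k, p=pi)
    draws = rng.random(t - 1)
    for step in range(1, t):
        path[step] = int(np.searchsorted(cum[path[step - 1]], draws[step - 1], side="right"))
    means = model.group_params[group_key].means
    noise = rng.normal(0.0, model.config.emission_noise_sd, size=(t, means.shape[1]))
    data = means[path] + noise
    run = TimeSeriesRun(
        subject_id=subject_id,
        run_id=run_id,
        data=data,
        channel_labels=[f"roi_{i + 1}" for i in range(means.shape[1])],
    )
    return run, path


@dataclass
class SimulatedCohort:
    """In-memory cohort plus its generating truth."""

    runs: list[TimeSeriesRun]
    phenotypes: list[SubjectRecord]
    truth: GroundTruthModel
    true_paths: dict[str, np.ndarray] = field(default_factory=dict)


_GROUP_TAGS = {g: f"{g[0][0]}{g[1][0].lower()}" for g in GROUP_KEYS}  # ga, ba, gc, bc


def simulate_cohort(config: GroundTruthConfig, out_dir: str | Path | None = None) -> SimulatedCohort:
    """Generate a full cohort; optionally write it in the ingestible formats.

    When ``out_dir`` is given, writes ``runs/<run_id>.tsv``, ``phenotypes.csv``
    and ``truth.json``.
    """
    model = make_ground_truth(config)
    tmin, tmax = config.run_length_range
    runs: list[TimeSeriesRun] = []
    phenotypes: list[SubjectRecord] = []
    true_paths: dict[str, np.ndarray] = {}
    for g_idx, g in enumerate(GROUP_KEYS):
        tag = _GROUP_TAGS[g]
        for r in range(config.runs_per_group[g_idx]):
            rng = derive_rng(config.seed, "run", g_idx, r)
            t = int(rng.integers(tmin, tmax + 1))
            subject_id = f"sub_{tag}{r:04d}"
            run_id = f"{subject_id}_run1"
            run, path = simulate_run(
                model, g, r, t, rng, subject_id=subject_id, run_id=run_id
            )
            runs.append(run)
            true_paths[run_id] = path
            sex, dx = g
            subtype = None
            if dx == "ADHD":
                subtype = ["combined", "inattentive", "hyperactive/impulsive"][r % 3]
            phenotypes.append(
                SubjectRecord(
                    subject_id=subject_id,
                    run_id=run_id,
                    sex=sex,
                    diagnosis=dx,
                    age=float(np.round(8.0 + 6.0 * rng.random(), 2)),
                    subtype=subtype,
                    site="sim",
                )
            )
    cohort = SimulatedCohort(runs=runs, phenotypes=phenotypes, truth=model, true_paths=true_paths)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SimulatedCohort, out_dir: Path) -> None:
    runs_dir = out_dir / "runs"
    runs_dir.mkdir(parents=True, exist_ok=True)
    for run in cohort.runs:
        write_roi_timeseries(run, runs_dir / f"{run.run_id}.tsv")
    write_phenotypes(cohort.phenotypes, out_dir / "phenotypes.csv")
    truth = {
        "seed": cohort.truth.seed,
        "n_states": cohort.truth.config.n_states,
        "n_channels": cohort.truth.config.n_channels,
        "templates": cohort.truth.templates.tolist(),
        "groups": {
            "|".join(g): {
                "transmat": cohort.truth.group_params[g].transmat.tolist(),
                "means": cohort.truth.group_params[g].means.tolist(),
            }
            for g in GROUP_KEYS
        },
        "true_paths": {rid: path.tolist() for rid, path in cohort.true_paths.items()},
    }
    (out_dir / "truth.json").write_text(json.dumps(truth))
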