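"""End-to-end orchestration: simulate -> ingest -> fit -> align -> metrics -> stats.

A single global seed deterministically derives every per-stage seed, so
re-running the same config yields byte-identical outputs. Each stage records
its inputs, outputs (with checksums), seed and wall time in a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import alignment as al
from . import dynamics as dyn
from . import hmm
from . import io_cohort as ioc
from . import stats as st
from . import synthetic as syn
from .errors import ValidationError
from .seeding import derive_seed

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ingest", "fit", "align", "metrics", "stats")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    enabled: bool = True
    n_states: int = 5
    n_channels: int = 20
    runs_per_group: list[int] = Field(default_factory=lambda: [10, 10, 10, 10])
    run_length_range: list[int] = Field(default_factory=lambda: [80, 230])
    on_diag_by_group: float | list[float] = 0.53
    template_separation: float = 2.0
    map_group_jitter_sd: float = 0.05
    emission_noise_sd: float = 1.0
    subject_tpm_jitter_sd: float | list[float] = 0.0
    tpm_jitter_mode: Literal["diagonal", "row"] = "diagonal"


class HmmConfig(_Strict):
    k: int | None = 5
    scan: list[int] | None = None  # [k_min, k_max]; overrides fixed k
    covariance: Literal["diagonal", "full"] = "diagonal"
    n_restarts: int = 5
    max_iter: int = 200
    tol: float = 1e-4

    @field_validator("scan")
    @classmethod
    def _scan_range(cls, v):
        if v is not None and (len(v) != 2 or v[0] < 1 or v[1] < v[0]):
            raise ValueError("scan must be [k_min, k_max] with 1 <= k_min <= k_max")
        return v


class AlignConfig(_Strict):
    k: int | None = None  # defaults to the fitted state count
    n_init: int = 50


class DynamicsConfig(_Strict):
    decoder: Literal["viterbi", "posterior_argmax"] = "viterbi"
    iti_convention: Literal["dwell", "dwell_minus_one"] = "dwell_minus_one"
    outlier_threshold_sd: float = 3.0


class StatsConfig(_Strict):
    ss_type: Literal["II", "III"] = "III"
    subsample: bool = True


class PipelineConfig(_Strict):
    cohort_dir: str = "cohort"
    output_dir: str = "output"
    seed: int = 0
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    hmm: HmmConfig = Field(default_factory=HmmConfig)
    alignment: AlignConfig = Field(default_factory=AlignConfig)
    dynamics: DynamicsConfig = Field(default_factory=DynamicsConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and fully validate a YAML config; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.stages: list[dict] = []

    def record(self, stage: str, seed: int, inputs: list[str], outputs: list[Path], dt: float):
        self.stages.append(
            {
                "stage": stage,
                "seed": seed,
                "inputs": inputs,
                "outputs": [
                    {"path": str(p), "sha256": _sha256(p)} for p in outputs if p.exists()
                ],
                "seconds": round(dt, 3),
            }
        )
        self.path.write_text(json.dumps({"stages": self.stages}, indent=1))


def _tag(group_key: tuple[str, str]) -> str:
    return f"{group_key[0]}_{group_key[1]}"


def run_pipeline(
    config: PipelineConfig, base_dir: str | Path = ".", through: str = "stats"
) -> dict:
    """Execute stages in order up to and including ``through``.

    Earlier stages always run (they are deterministic under the config seed,
    so re-running reproduces identical outputs). Any stage failure propagates
    with the stage name; outputs of completed stages are preserved.
    """
    if through not in STAGES:
        raise ValidationError(f"unknown stage {through!r}; valid: {STAGES}")
    stop_at = STAGES.index(through)

    def _done(stage: str) -> bool:
        return STAGES.index(stage) >= stop_at

    base = Path(base_dir)
    cohort_dir = base / config.cohort_dir
    out_dir = base / config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir / "manifest.json")
    master = config.seed

    # -- simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    sim_seed = derive_seed(master, "simulate")
    if config.simulate.enabled:
        gt_config = syn.GroundTruthConfig(
            n_states=config.simulate.n_states,
            n_channels=config.simulate.n_channels,
            runs_per_group=tuple(config.simulate.runs_per_group),
            run_length_range=tuple(config.simulate.run_length_range),
            on_diag_by_group=_maybe_tuple(config.simulate.on_diag_by_group),
            template_separation=config.simulate.template_separation,
            map_group_jitter_sd=config.simulate.map_group_jitter_sd,
            emission_noise_sd=config.simulate.emission_noise_sd,
            subject_tpm_jitter_sd=_maybe_tuple(config.simulate.subject_tpm_jitter_sd),
            tpm_jitter_mode=config.simulate.tpm_jitter_mode,
            seed=sim_seed,
        )
        syn.simulate_cohort(gt_config, out_dir=cohort_dir)
        logger.info("simulate: wrote cohort to %s", cohort_dir)
    elif not cohort_dir.exists():
        raise ValidationError(f"cohort directory does not exist: {cohort_dir}")
    manifest.record(
        "simulate", sim_seed, [], sorted((cohort_dir).glob("*.csv")), time.perf_counter() - t0
    )
    if _done("simulate"):
        return {"stages": manifest.stages}

    # -- ingest ------------------------------------------------------------
    t0 = time.perf_counter()
    raw_runs, phenotypes = ioc.load_cohort(cohort_dir)
    runs = [ioc.zscore_run(r) for r in raw_runs]
    groups = ioc.assemble_groups(runs, phenotypes)
    ingest_dir = out_dir / "ingest"
    ingest_dir.mkdir(exist_ok=True)
    boundaries_index = {}
    ingest_outputs = []
    for g, ds in groups.items():
        path = ingest_dir / f"{_tag(g)}.tsv"
        np.savetxt(path, ds.concatenated(), delimiter="\t")
        boundaries_index[_tag(g)] = {
            "runs": [r.run_id for r in ds.runs],
            "boundaries": ds.boundaries,
        }
        ingest_outputs.append(path)
    bpath = ingest_dir / "boundaries.json"
    bpath.write_text(json.dumps(boundaries_index))
    ingest_outputs.append(bpath)
    manifest.record(
        "ingest", master, [str(cohort_dir)], ingest_outputs, time.perf_counter() - t0
    )
    if _done("ingest"):
        return {"stages": manifest.stages}

    # -- fit ---------------------------------------------------------------
    t0 = time.perf_counter()
    fit_dir = out_dir / "models"
    fit_dir.mkdir(exist_ok=True)
    fitted: dict[tuple[str, str], hmm.HMMParams] = {}
    fit_outputs = []
    selected_k = config.hmm.k
    if config.hmm.scan is not None:
        # scan every group first, then share one K (modal elbow pick,
        # smallest on ties) so alignment is well-defined
        scans: dict[tuple[str, str], hmm.FitScan] = {}
        picks = []
        for g, ds in groups.items():
            scan = hmm.scan_states(
                ds.concatenated(),
                ds.boundaries,
                k_min=config.hmm.scan[0],
                k_max=config.hmm.scan[1],
                covariance=config.hmm.covariance,
                n_restarts=config.hmm.n_restarts,
                max_iter=config.hmm.max_iter,
                tol=config.hmm.tol,
                seed=derive_seed(master, "fit", _tag(g)),
            )
            scans[g] = scan
            pd.DataFrame(
                {
                    "k": scan.k_values(),
                    "log_likelihood": scan.log_likelihoods(),
                    "converged": [e.converged for e in scan.entries],
                }
            ).to_csv(fit_dir / f"scan_{_tag(g)}.csv", index=False)
            fit_outputs.append(fit_dir / f"scan_{_tag(g)}.csv")
            picks.append(hmm.select_elbow(scan).selected_k)
        selected_k = min(
            sorted(set(picks)), key=lambda k: (-picks.count(k), k)
        )
        logger.info("fit: per-group elbow picks %s -> shared K=%d", picks, selected_k)
        for g in groups:
            fitted[g] = next(
                e.params for e in scans[g].entries if e.k == selected_k
            )
    else:
        for g, ds in groups.items():
            fitted[g], _ = hmm.em_fit(
                ds.concatenated(),
                ds.boundaries,
                k=config.hmm.k,
                covariance=config.hmm.covariance,
                n_restarts=config.hmm.n_restarts,
                max_iter=config.hmm.max_iter,
                tol=config.hmm.tol,
                seed=derive_seed(master, "fit", _tag(g)),
            )
    for g in groups:
        fit_outputs.append(fitted[g].save(fit_dir / f"hmm_{_tag(g)}.json"))
    manifest.record(
        "fit", derive_seed(master, "fit"), [str(ingest_dir)], fit_outputs,
        time.perf_counter() - t0,
    )
    if _done("fit"):
        return {"stages": manifest.stages}

    # -- align -------------------------------------------------------------
    t0 = time.perf_counter()
    maps = [al.extract_state_maps(fitted[g], g) for g in ioc.GROUP_KEYS]
    align_k = config.alignment.k or selected_k
    assignment = al.cluster_state_maps(
        maps, k=align_k, n_init=config.alignment.n_init,
        seed=derive_seed(master, "align"),
    )
    consensus = al.consensus_maps(maps, assignment)
    align_dir = out_dir / "alignment"
    al.save_alignment(consensus, assignment, align_dir)
    manifest.record(
        "align", derive_seed(master, "align"), [str(fit_dir)],
        sorted(align_dir.iterdir()), time.perf_counter() - t0,
    )
    if _done("align"):
        return {"stages": manifest.stages}

    # -- metrics -----------------------------------------------------------
    t0 = time.perf_counter()
    k = align_k
    records = []
    run_groups = {}
    seqs_by_group: dict[tuple[str, str], list[dyn.StateSequence]] = {}
    for g, ds in groups.items():
        seqs_by_group[g] = []
        for run in ds.runs:
            seq = dyn.decode_run(
                fitted[g], consensus.relabeling[g], run, config.dynamics.decoder
            )
            seqs_by_group[g].append(seq)
            records.append(dyn.compute_record(seq, k, config.dynamics.iti_convention))
            run_groups[run.run_id] = g
    df = dyn.records_to_frame(records, k, run_groups)
    df, outlier_reports = dyn.apply_outlier_flags(
        df, config.dynamics.outlier_threshold_sd
    )
    metrics_dir = out_dir / "metrics"
    metrics_dir.mkdir(exist_ok=True)
    df.to_csv(metrics_dir / "dynamics.csv", index=False)
    fo_group = pd.DataFrame(
        {
            _tag(g): dyn.fractional_occupancy(seqs_by_group[g], k, level="group")
            for g in ioc.GROUP_KEYS
        },
        index=[f"state_{s + 1}" for s in range(k)],
    )
    fo_group.to_csv(metrics_dir / "fo_group.csv")
    metrics_outputs = [metrics_dir / "dynamics.csv", metrics_dir / "fo_group.csv"]
    for g in ioc.GROUP_KEYS:
        pooled = np.zeros((k, k), dtype=int)
        for seq in seqs_by_group[g]:
            pooled += dyn.empirical_transitions(seq, k).counts
        with np.errstate(invalid="ignore"):
            tpm = pooled / pooled.sum(axis=1, keepdims=True)
        path = metrics_dir / f"tpm_{_tag(g)}.csv"
        pd.DataFrame(
            tpm,
            index=[f"from_{s + 1}" for s in range(k)],
            columns=[f"to_{s + 1}" for s in range(k)],
        ).to_csv(path)
        metrics_outputs.append(path)
    manifest.record(
        "metrics", master, [str(align_dir)], metrics_outputs, time.perf_counter() - t0
    )
    if _done("metrics"):
        return {"stages": manifest.stages}

    # -- stats -------------------------------------------------------------
    t0 = time.perf_counter()
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(exist_ok=True)
    stats_outputs = []
    iti_df = df[~df["outlier_iti"]]
    nt_df = df[~df["outlier_nt"]]
    tables = {
        "anova_iti_mean": st.two_way_anova(
            iti_df["iti_mean"].to_numpy(), iti_df["sex"].to_numpy(),
            iti_df["dx"].to_numpy(), config.stats.ss_type,
        ),
        "anova_iti_sd": st.two_way_anova(
            iti_df["iti_sd"].to_numpy(), iti_df["sex"].to_numpy(),
            iti_df["dx"].to_numpy(), config.stats.ss_type,
        ),
        "anova_nt": st.two_way_anova(
            nt_df["nt"].to_numpy(), nt_df["sex"].to_numpy(),
            nt_df["dx"].to_numpy(), config.stats.ss_type,
        ),
        "anova_fo_mixed": st.mixed_anova_fo(
            df[[f"fo_{s + 1}" for s in range(k)]].to_numpy(),
            df["sex"].to_numpy(), df["dx"].to_numpy(),
        ),
    }
    for name, table in tables.items():
        path = stats_dir / f"{name}.csv"
        table.to_frame().to_csv(path, index=False)
        stats_outputs.append(path)

    statewise = []
    for grouping, col in (("sex", "iti_state_"), ("dx", "iti_sd_state_")):
        long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "state": s + 1,
                        "value": iti_df[f"{col}{s + 1}"],
                        grouping: iti_df[grouping],
                    }
                )
                for s in range(k)
            ]
        )
        for row in st.state_wise_tests(long, grouping):
            statewise.append({"grouping": grouping, **row.__dict__})
    pd.DataFrame(statewise).to_csv(stats_dir / "statewise_tests.csv", index=False)
    stats_outputs.append(stats_dir / "statewise_tests.csv")

    both = df[~df["outlier_iti"] & ~df["outlier_nt"]]
    r, p = st.iti_nt_correlation(both)
    (stats_dir / "correlation.json").write_text(
        json.dumps({"r": r, "p": p, "n": int(len(both))})
    )
    stats_outputs.append(stats_dir / "correlation.json")

    if config.stats.subsample:
        sub_dir = stats_dir / "subsample"
        sub_dir.mkdir(exist_ok=True)
        result = st.subsample_analysis(iti_df, derive_seed(master, "subsample"))
        for name, table in result.tables.items():
            path = sub_dir / f"anova_{name}.csv"
            table.to_frame().to_csv(path, index=False)
            stats_outputs.append(path)
    manifest.record(
        "stats", derive_seed(master, "stats"), [str(metrics_dir)], stats_outputs,
        time.perf_counter() - t0,
    )

    logger.info("pipeline complete: %s", manifest.path)
    return {"stages": manifest.stages, "outlier_reports": {
        name: [rid for rid, _ in rep.removed] for name, rep in outlier_reports.items()
    }}


def _maybe_tuple(v):
    return tuple(v) if isinstance(v, list) else v


def analyze_cohort(
    runs: list[ioc.TimeSeriesRun],
    phenotypes: list[ioc.SubjectRecord],
    k: int,
    seed: int = 0,
    n_restarts: int = 2,
    max_iter: int = 100,
    tol: float = 1e-7,
    decoder: str = "viterbi",
    iti_convention: str = "dwell_minus_one",
    align_n_init: int = 50,
    outlier_threshold_sd: float = 3.0,
):
    """In-memory ingest -> fit -> align -> metrics on an already-loaded cohort.

    Returns ``(metrics_df, fitted_params_by_group, consensus)`` where the
    metrics frame has one row per run with outlier flags applied. Raw runs
    are z-scored here; pass them unscaled.
    """
    z_runs = [ioc.zscore_run(r) for r in runs]
    groups = ioc.assemble_groups(z_runs, phenotypes)
    fitted: dict[tuple[str, str], hmm.HMMParams] = {}
    for g, ds in groups.items():
        fitted[g], _ = hmm.em_fit(
            ds.concatenated(), ds.boundaries, k=k, n_restarts=n_restarts,
            max_iter=max_iter, tol=tol, seed=derive_seed(seed, "fit", _tag(g)),
        )
    maps = [al.extract_state_maps(fitted[g], g) for g in ioc.GROUP_KEYS]
    assignment = al.cluster_state_maps(
        maps, k=k, n_init=align_n_init, seed=derive_seed(seed, "align")
    )
    if assignment.valid:
        consensus = al.consensus_maps(maps, assignment)
        relabeling = consensus.relabeling
    else:
        # fall back to local labels so metrics remain computable
        logger.warning("analyze_cohort: invalid alignment; keeping local labels")
        consensus = None
        relabeling = {g: np.arange(k) for g in ioc.GROUP_KEYS}
    records, run_groups = [], {}
    for g, ds in groups.items():
        for run in ds.runs:
            seq = dyn.decode_run(fitted[g], relabeling[g], run, decoder)
            records.append(dyn.compute_record(seq, k, iti_convention))
            run_groups[run.run_id] = g
    df = dyn.records_to_frame(records, k, run_groups)
    df, _ = dyn.apply_outlier_flags(df, outlier_threshold_sd)
    return df, fitted, consensus
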