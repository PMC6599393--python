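"""Cohort ingestion: ROI time-course files, phenotype tables, grouping.

Each scan run is a plain-text matrix with rows = time points and columns =
parcels. Runs are z-scored individually (per channel, sample SD) and then
concatenated within their sex x diagnosis group; run boundaries are kept so
run identity is never lost inside the concatenation.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConstantChannelError,
    DegenerateInputError,
    FormatError,
    ParseError,
    ValidationError,
)

SEXES = ("girl", "boy")
DIAGNOSES = ("ADHD", "control")
#: Canonical group order (matches the cohort characteristics table).
GROUP_KEYS = (
    ("girl", "ADHD"),
    ("boy", "ADHD"),
    ("girl", "control"),
    ("boy", "control"),
)

SUBTYPES = ("hyperactive/impulsive", "inattentive", "combined", "none")


@dataclass
class TimeSeriesRun:
    """One scan's T x C parcel signal matrix plus identifiers."""

    subject_id: str
    run_id: str
    data: np.ndarray
    channel_labels: list[str]
    site: str | None = None
    tr_seconds: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(f"run {self.run_id}: data must be 2-D")
        t, c = self.data.shape
        if t < 2:
            raise DegenerateInputError(f"run {self.run_id}: T={t} < 2 time points")
        if c < 1:
            raise ValidationError(f"run {self.run_id}: C={c} < 1 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(f"run {self.run_id}: non-finite values in data")
        if len(self.channel_labels) != c:
            raise ValidationError(
                f"run {self.run_id}: {len(self.channel_labels)} labels for {c} channels"
            )
        if len(set(self.channel_labels)) != c:
            raise ValidationError(f"run {self.run_id}: duplicate channel labels")
        if self.tr_seconds is not None and self.tr_seconds <= 0:
            raise ValidationError(f"run {self.run_id}: tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SubjectRecord:
    """Phenotype row for one scan run."""

    subject_id: str
    run_id: str
    sex: str
    diagnosis: str
    age: float | None = None
    subtype: str | None = None
    site: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(
                f"phenotype {self.subject_id}/{self.run_id}: sex {self.sex!r} not in {SEXES}"
            )
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(
                f"phenotype {self.subject_id}/{self.run_id}: diagnosis "
                f"{self.diagnosis!r} not in {DIAGNOSES}"
            )
        if self.age is not None and self.age < 0:
            raise ValidationError(
                f"phenotype {self.subject_id}/{self.run_id}: negative age"
            )
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise ValidationError(
                f"phenotype {self.subject_id}/{self.run_id}: subtype {self.subtype!r}"
            )

    @property
    def group_key(self) -> tuple[str, str]:
        return (self.sex, self.diagnosis)


@dataclass
class GroupDataset:
    """All runs of one sex x diagnosis cell, with concatenation bookkeeping."""

    group_key: tuple[str, str]
    runs: list[TimeSeriesRun]
    #: (start, length) of each run inside the concatenated matrix.
    boundaries: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.boundaries:
            start = 0
            bounds = []
            for run in self.runs:
                bounds.append((start, run.n_timepoints))
                start += run.n_timepoints
            self.boundaries = bounds
        total = sum(length for _, length in self.boundaries)
        expected = sum(run.n_timepoints for run in self.runs)
        if total != expected:
            raise ValidationError(
                f"group {self.group_key}: boundaries cover {total} rows, runs have {expected}"
            )

    @property
    def n_channels(self) -> int:
        return self.runs[0].n_channels

    def concatenated(self) -> np.ndarray:
        """T_total x C stacked matrix in run order."""
        return np.vstack([run.data for run in self.runs])


_DIALECT_DELIMS = {"whitespace": None, "tsv": "\t", "csv": ","}


def _split_line(line: str, delim: str | None) -> list[str]:
    if delim is None:
        return line.split()
    return [tok.strip() for tok in line.split(delim)]


def _detect_dialect(line: str) -> str:
    if "\t" in line:
        return "tsv"
    if "," in line:
        return "csv"
    return "whitespace"


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_roi_timeseries(
    path: str | Path,
    dialect: str = "auto",
    subject_id: str | None = None,
    run_id: str | None = None,
) -> TimeSeriesRun:
    """Read one ROI time-course file (rows = time points, columns = parcels).

    Lines starting with ``#`` are comments. A leading non-numeric row is used
    as channel labels; otherwise labels are auto-generated ``roi_1..roi_C``.
    Identifiers default to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such time-course file: {path}")
    raw = [
        (i + 1, line.strip())
        for i, line in enumerate(path.read_text().splitlines())
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not raw:
        raise FormatError(f"{path}: no data rows")
    if dialect == "auto":
        dialect = _detect_dialect(raw[0][1])
    if dialect not in _DIALECT_DELIMS:
        raise ValidationError(f"unknown dialect {dialect!r}")
    delim = _DIALECT_DELIMS[dialect]

    first_tokens = _split_line(raw[0][1], delim)
    header: list[str] | None = None
    if not all(_is_number(tok) for tok in first_tokens):
        header = first_tokens
        raw = raw[1:]
    if len(raw) < 2:
        raise DegenerateInputError(f"{path}: fewer than 2 data rows")

    n_cols = len(_split_line(raw[0][1], delim))
    rows = np.empty((len(raw), n_cols))
    for r, (lineno, line) in enumerate(raw):
        tokens = _split_line(line, delim)
        if len(tokens) != n_cols:
            raise FormatError(
                f"{path}: line {lineno} has {len(tokens)} fields, expected {n_cols}"
            )
        for c, tok in enumerate(tokens):
            try:
                rows[r, c] = float(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {tok!r} at line {lineno}, column {c + 1}"
                ) from None
    if header is not None and len(header) != n_cols:
        raise FormatError(
            f"{path}: header has {len(header)} labels for {n_cols} columns"
        )
    labels = header if header is not None else [f"roi_{i + 1}" for i in range(n_cols)]
    stem = path.stem
    return TimeSeriesRun(
        subject_id=subject_id or stem,
        run_id=run_id or stem,
        data=rows,
        channel_labels=labels,
    )


def write_roi_timeseries(
    run: TimeSeriesRun, path: str | Path, dialect: str = "tsv", header: bool = True
) -> Path:
    """Write a run so that :func:`read_roi_timeseries` round-trips it exactly."""
    path = Path(path)
    delim = _DIALECT_DELIMS.get(dialect) or ("\t" if dialect == "whitespace" else None)
    if dialect == "whitespace":
        delim = " "
    if delim is None:
        raise ValidationError(f"unknown dialect {dialect!r}")
    buf = io.StringIO()
    if header:
        buf.write(delim.join(run.channel_labels) + "\n")
    for row in run.data:
        buf.write(delim.join(repr(float(v)) for v in row) + "\n")
    path.write_text(buf.getvalue())
    return path


def zscore_run(run: TimeSeriesRun) -> TimeSeriesRun:
    """Z-score each channel of one run (sample SD, denominator T-1)."""
    mean = run.data.mean(axis=0)
    sd = run.data.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        names = ", ".join(run.channel_labels[i] for i in bad)
        raise ConstantChannelError(
            f"run {run.run_id}: constant channel(s) cannot be z-scored: {names}"
        )
    return replace(run, data=(run.data - mean) / sd)


def read_phenotypes(path: str | Path) -> list[SubjectRecord]:
    """Read the phenotype CSV (subject_id, run_id, sex, dx, age, subtype, site)."""
    path = Path(path)
    records: list[SubjectRecord] = []
    seen: set[tuple[str, str]] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "run_id", "sex", "dx"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            key = (row["subject_id"], row["run_id"])
            if key in seen:
                raise ValidationError(f"{path}: duplicate (subject_id, run_id) {key}")
            seen.add(key)
            age = row.get("age") or None
            subtype = row.get("subtype") or None
            records.append(
                SubjectRecord(
                    subject_id=row["subject_id"],
                    run_id=row["run_id"],
                    sex=row["sex"],
                    diagnosis=row["dx"],
                    age=float(age) if age is not None else None,
                    subtype=subtype,
                    site=row.get("site") or None,
                )
            )
    return records


def write_phenotypes(records: Sequence[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "run_id", "sex", "dx", "age", "subtype", "site"])
        for r in records:
            writer.writerow(
                [
                    r.subject_id,
                    r.run_id,
                    r.sex,
                    r.diagnosis,
                    "" if r.age is None else r.age,
                    r.subtype or "",
                    r.site or "",
                ]
            )
    return path


def assemble_groups(
    runs: Sequence[TimeSeriesRun], phenotypes: Sequence[SubjectRecord]
) -> dict[tuple[str, str], GroupDataset]:
    """Partition runs into the four sex x diagnosis groups.

    Multiple scans of one subject are separate analysis units. Raises if any
    run lacks a phenotype row or the channel counts disagree.
    """
    pheno_by_key = {(p.subject_id, p.run_id): p for p in phenotypes}
    orphans = [
        f"{r.subject_id}/{r.run_id}"
        for r in runs
        if (r.subject_id, r.run_id) not in pheno_by_key
    ]
    if orphans:
        raise ValidationError(f"runs without phenotype rows: {', '.join(orphans)}")
    if runs:
        c0 = runs[0].n_channels
        for r in runs:
            if r.n_channels != c0:
                raise ValidationError(
                    f"run {r.run_id} has {r.n_channels} channels, expected {c0}"
                )
    grouped: dict[tuple[str, str], list[TimeSeriesRun]] = {k: [] for k in GROUP_KEYS}
    for r in runs:
        grouped[pheno_by_key[(r.subject_id, r.run_id)].group_key].append(r)
    return {
        key: GroupDataset(group_key=key, runs=members)
        for key, members in grouped.items()
    }


def load_cohort(
    cohort_dir: str | Path,
) -> tuple[list[TimeSeriesRun], list[SubjectRecord]]:
    """Read ``runs/*`` and ``phenotypes.csv`` from a cohort directory.

    Each run file's stem is its run_id; subject identity comes from the
    phenotype table. Runs without a phenotype row fail in assemble_groups.
    """
    cohort_dir = Path(cohort_dir)
    phenotypes = read_phenotypes(cohort_dir / "phenotypes.csv")
    by_run_id = {p.run_id: p for p in phenotypes}
    runs = []
    for path in sorted((cohort_dir / "runs").iterdir()):
        pheno = by_run_id.get(path.stem)
        runs.append(
            read_roi_timeseries(
                path,
                subject_id=pheno.subject_id if pheno else path.stem,
                run_id=path.stem,
            )
        )
    return runs, phenotypes


def group_counts(phenotypes: Sequence[SubjectRecord]) -> pd.Series:
    """Cross-tabulation of phenotype rows by group, in canonical order."""
    counts = {key: 0 for key in GROUP_KEYS}
    for p in phenotypes:
        counts[p.group_key] += 1
    idx = pd.MultiIndex.from_tuples(GROUP_KEYS, names=["sex", "dx"])
    return pd.Series([counts[k] for k in GROUP_KEYS], index=idx, name="n_runs")
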