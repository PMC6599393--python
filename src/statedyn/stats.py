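"""Group inference: factorial ANOVAs, effect sizes, per-state tests.

The 2x2 (sex x diagnosis) between-run ANOVA uses Type III sums of squares
with sum-to-zero contrasts by default (Type II available), computed by
model comparison. The repeated-measures FO analysis treats the run as the
repeated unit with state as the within factor; between-run variation is
absorbed by run-wise centering, which is exact here because every run
contributes all K states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, StateDynError, ValidationError
from .io_cohort import DIAGNOSES, GROUP_KEYS, SEXES
from .seeding import derive_rng


@dataclass
class AnovaTable:
    """Effect rows (SS, df, F, p, partial eta squared) plus the error stratum."""

    effects: pd.DataFrame
    ss_error: float
    df_error: int
    design: str = ""

    def row(self, effect: str) -> pd.Series:
        match = self.effects[self.effects["effect"] == effect]
        if match.empty:
            raise KeyError(f"no effect {effect!r} in table ({self.design})")
        return match.iloc[0]

    def to_frame(self) -> pd.DataFrame:
        err = pd.DataFrame(
            [
                {
                    "effect": "error",
                    "ss": self.ss_error,
                    "df": self.df_error,
                    "F": np.nan,
                    "p": np.nan,
                    "partial_eta_sq": np.nan,
                }
            ]
        )
        return pd.concat([self.effects, err], ignore_index=True)


def cohens_d(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> float:
    """Pooled-SD standardized mean difference, signed second minus first."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("cohens_d needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("negative SD")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        if m1 == m2:
            return 0.0
        raise StateDynError("zero pooled SD with unequal means: infinite effect size")
    return (m2 - m1) / float(np.sqrt(pooled_var))


def _codes(sex: np.ndarray, dx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum-to-zero codes: girl/ADHD = +1, boy/control = -1."""
    xs = np.where(np.asarray(sex) == SEXES[0], 1.0, -1.0)
    xd = np.where(np.asarray(dx) == DIAGNOSES[0], 1.0, -1.0)
    return xs, xd


def _sse(x: np.ndarray, y: np.ndarray) -> float:
    resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
    return float(resid @ resid)


def _f_row(name: str, ss: float, df: int, ss_err: float, df_err: int) -> dict:
    ss = max(ss, 0.0)
    ms_err = ss_err / df_err
    f = (ss / df) / ms_err if ms_err > 0 else np.nan
    p = float(sps.f.sf(f, df, df_err)) if np.isfinite(f) else np.nan
    pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
    return {"effect": name, "ss": ss, "df": df, "F": f, "p": p, "partial_eta_sq": pes}


def two_way_anova(
    values: np.ndarray,
    sex: np.ndarray,
    dx: np.ndarray,
    ss_type: str = "III",
) -> AnovaTable:
    """Sex x diagnosis between-run ANOVA with partial eta squared.

    Type III drops each sum-to-zero coded term from the full model; Type II
    respects marginality for the main effects. Requires >= 2 runs per cell.
    """
    if ss_type not in ("II", "III"):
        raise ValidationError(f"ss_type must be 'II' or 'III', got {ss_type!r}")
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    dx = np.asarray(dx)
    for s_level, d_level in GROUP_KEYS:
        n_cell = int(np.sum((sex == s_level) & (dx == d_level)))
        if n_cell < 2:
            raise DesignError(
                f"cell ({s_level}, {d_level}) has {n_cell} runs; need >= 2"
            )
    xs, xd = _codes(sex, dx)
    ones = np.ones_like(xs)
    full = np.column_stack([ones, xs, xd, xs * xd])
    n = values.size
    sse_full = _sse(full, values)
    df_err = n - 4

    def drop(*cols: int) -> float:
        keep = [i for i in range(4) if i not in cols]
        return _sse(full[:, keep], values) - sse_full

    if ss_type == "III":
        ss_sex, ss_dx = drop(1), drop(2)
    else:
        both_mains = np.column_stack([ones, xs, xd])
        ss_sex = _sse(np.column_stack([ones, xd]), values) - _sse(both_mains, values)
        ss_dx = _sse(np.column_stack([ones, xs]), values) - _sse(both_mains, values)
    ss_int = drop(3)

    rows = [
        _f_row("sex", ss_sex, 1, sse_full, df_err),
        _f_row("dx", ss_dx, 1, sse_full, df_err),
        _f_row("sex:dx", ss_int, 1, sse_full, df_err),
    ]
    return AnovaTable(
        effects=pd.DataFrame(rows),
        ss_error=sse_full,
        df_error=df_err,
        design=f"sex*dx between-runs, type {ss_type}",
    )


def mixed_anova_fo(
    fo: np.ndarray, sex: np.ndarray, dx: np.ndarray
) -> AnovaTable:
    """Repeated-measures ANOVA on run-level FO: state within, sex x dx between.

    Within-effect SS are Type III model comparisons on run-centered FO; the
    error stratum is the state x run residual. Because FO rows sum to 1 the
    between-run section is degenerate (run means are constant) and only the
    within-state effects are reported - including the sex x dx x state
    interaction the analysis exists for.
    """
    fo = np.asarray(fo, dtype=float)
    if fo.ndim != 2 or fo.shape[1] < 2:
        raise DesignError("mixed FO ANOVA needs runs x K with K >= 2")
    n, k = fo.shape
    xs, xd = _codes(sex, dx)
    y = (fo - fo.mean(axis=1, keepdims=True)).ravel()  # run-centered, long format

    contrasts = np.eye(k)[:, :-1] - 1.0 / k  # sum-to-zero state coding, K-1 columns
    state_block = np.tile(contrasts, (n, 1))
    rep = np.repeat(np.arange(n), k)
    blocks = {
        "state": state_block,
        "state:sex": state_block * xs[rep, None],
        "state:dx": state_block * xd[rep, None],
        "state:sex:dx": state_block * (xs * xd)[rep, None],
    }
    full = np.column_stack(list(blocks.values()))
    sse_full = _sse(full, y)
    df_err = (k - 1) * (n - 4)
    if df_err < 1:
        raise DesignError("not enough runs for the repeated-measures error stratum")

    rows = []
    names = list(blocks)
    for i, name in enumerate(names):
        keep = np.column_stack([blocks[m] for j, m in enumerate(names) if j != i])
        ss = _sse(keep, y) - sse_full
        rows.append(_f_row(name, ss, k - 1, sse_full, df_err))
    return AnovaTable(
        effects=pd.DataFrame(rows),
        ss_error=sse_full,
        df_error=df_err,
        design="FO repeated measures: state within, sex*dx between, type III",
    )


@dataclass
class StateTestRow:
    state: int  # 1-based, as reported
    m1: float
    sd1: float
    n1: int
    m2: float
    sd2: float
    n2: int
    p: float
    cohens_d: float
    testable: bool = True


def state_wise_tests(
    per_state_values: pd.DataFrame,
    grouping: str,
) -> list[StateTestRow]:
    """Per-state pooled-variance two-sample tests with Cohen's d.

    ``per_state_values`` has one row per run with columns ``state`` (1..K),
    ``value`` and the grouping column (``sex`` or ``dx``); missing values
    (states the run never visited) are excluded. The first factor level
    (girl / ADHD) is group 1; d is signed group2 - group1.
    """
    if grouping not in ("sex", "dx"):
        raise ValidationError(f"grouping must be 'sex' or 'dx', got {grouping!r}")
    levels = SEXES if grouping == "sex" else DIAGNOSES
    rows: list[StateTestRow] = []
    for state in sorted(per_state_values["state"].unique()):
        sub = per_state_values[per_state_values["state"] == state].dropna(
            subset=["value"]
        )
        g1 = sub.loc[sub[grouping] == levels[0], "value"].to_numpy()
        g2 = sub.loc[sub[grouping] == levels[1], "value"].to_numpy()
        if g1.size < 2 or g2.size < 2:
            rows.append(
                StateTestRow(
                    state=int(state),
                    m1=np.nan, sd1=np.nan, n1=g1.size,
                    m2=np.nan, sd2=np.nan, n2=g2.size,
                    p=np.nan, cohens_d=np.nan, testable=False,
                )
            )
            continue
        stat = sps.ttest_ind(g1, g2, equal_var=True)
        d = cohens_d(
            g1.mean(), g1.std(ddof=1), g1.size, g2.mean(), g2.std(ddof=1), g2.size
        )
        rows.append(
            StateTestRow(
                state=int(state),
                m1=float(g1.mean()), sd1=float(g1.std(ddof=1)), n1=g1.size,
                m2=float(g2.mean()), sd2=float(g2.std(ddof=1)), n2=g2.size,
                p=float(stat.pvalue), cohens_d=float(d),
            )
        )
    return rows


def holm_correction(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p values (optional; raw p is the default report)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adjusted = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()


def iti_nt_correlation(df: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of run-level ITI mean and NT (post screening)."""
    sub = df.dropna(subset=["iti_mean", "nt"])
    if len(sub) < 3:
        raise DesignError("correlation needs >= 3 runs")
    x = sub["iti_mean"].to_numpy()
    y = sub["nt"].to_numpy()
    if x.std() == 0.0 or y.std() == 0.0:
        raise DesignError("zero variance in ITI or NT; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class SubsampleResult:
    tables: dict[str, AnovaTable]
    selected_run_ids: list[str]
    n_per_group: int


def subsample_analysis(
    df: pd.DataFrame,
    seed: int,
    metrics: tuple[str, ...] = ("iti_mean", "iti_sd", "nt"),
) -> SubsampleResult:
    """Match every group to the smallest group's size and rerun the ANOVAs.

    Draws without replacement ``n_min`` runs from each larger group, where
    ``n_min`` is the smallest cell count; fully deterministic under ``seed``.
    """
    counts = {g: int(((df["sex"] == g[0]) & (df["dx"] == g[1])).sum()) for g in GROUP_KEYS}
    n_min = min(counts.values())
    if n_min < 10:
        warnings.warn(
            f"subsample size {n_min} < 10: underpowered comparison", stacklevel=2
        )
    rng = derive_rng(seed, "subsample")
    selected: list[str] = []
    for g in GROUP_KEYS:
        ids = df.loc[(df["sex"] == g[0]) & (df["dx"] == g[1]), "run_id"].tolist()
        if len(ids) == n_min:
            selected.extend(ids)
        else:
            selected.extend(rng.choice(ids, size=n_min, replace=False).tolist())
    sub = df[df["run_id"].isin(selected)]
    tables = {
        m: two_way_anova(
            sub[m].to_numpy(), sub["sex"].to_numpy(), sub["dx"].to_numpy()
        )
        for m in metrics
        if m in sub.columns and np.isfinite(sub[m].to_numpy(dtype=float)).all()
    }
    return SubsampleResult(tables=tables, selected_run_ids=sorted(selected), n_per_group=n_min)
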