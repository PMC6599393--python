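"""Cross-group state alignment via k-means on state mean-activation maps.

Each group's HMM is fitted independently, so state 2 of one group need not
mean what state 2 of another does. Clustering the per-state emission-mean
vectors of all groups matches equivalent states: a valid assignment puts
exactly one map from each group in every cluster. Consensus maps average the
matched maps; consensus labels are ordered by descending total absolute
activation so the numbering is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import AlignmentError, ValidationError
from .hmm import HMMParams

GroupKey = tuple[str, str]


@dataclass
class StateMaps:
    """Per-state emission-mean vectors (K x C) of one group's model."""

    group_key: GroupKey
    maps: np.ndarray
    state_ids: list[int]

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if not np.all(np.isfinite(self.maps)):
            raise ValidationError(f"group {self.group_key}: non-finite state maps")
        if len(self.state_ids) != self.maps.shape[0]:
            raise ValidationError(f"group {self.group_key}: state_ids/maps mismatch")


@dataclass
class ValidityReport:
    valid: bool
    #: (cluster_id, group_key, count) for every cluster/group cell with count != 1
    violations: list[tuple[int, GroupKey, int]]


@dataclass
class ClusterAssignment:
    """k-means result over all groups' maps."""

    entries: dict[tuple[GroupKey, int], int]
    centroids: np.ndarray
    inertia: float
    valid: bool
    report: ValidityReport


def extract_state_maps(params: HMMParams, group_key: GroupKey) -> StateMaps:
    """The emission means, one row per state, unmodified."""
    return StateMaps(
        group_key=group_key,
        maps=params.means.copy(),
        state_ids=list(range(params.n_states)),
    )


def save_state_maps(maps: StateMaps, path: str | Path) -> Path:
    df = pd.DataFrame(
        maps.maps,
        index=[f"state_{s}" for s in maps.state_ids],
        columns=[f"ch_{i}" for i in range(maps.maps.shape[1])],
    )
    df.to_csv(path, float_format=None)
    return Path(path)


def load_state_maps(path: str | Path, group_key: GroupKey) -> StateMaps:
    df = pd.read_csv(path, index_col=0)
    state_ids = [int(s.split("_")[1]) for s in df.index]
    return StateMaps(group_key=group_key, maps=df.to_numpy(), state_ids=state_ids)


def _check_validity(
    entries: dict[tuple[GroupKey, int], int],
    groups: Sequence[GroupKey],
    k: int,
) -> ValidityReport:
    violations = []
    for cluster in range(k):
        for g in groups:
            count = sum(
                1
                for (gk, _), cl in entries.items()
                if cl == cluster and gk == g
            )
            if count != 1:
                violations.append((cluster, g, count))
    return ValidityReport(valid=not violations, violations=violations)


def cluster_state_maps(
    maps: Sequence[StateMaps], k: int, n_init: int = 50, seed: int = 0
) -> ClusterAssignment:
    """k-means (Euclidean, best of ``n_init`` inits) over all groups' maps."""
    total = sum(m.maps.shape[0] for m in maps)
    if k > total:
        raise ValidationError(f"k={k} exceeds the {total} available maps")
    x = np.vstack([m.maps for m in maps])
    keys = [(m.group_key, s) for m in maps for s in m.state_ids]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed % (2**32)).fit(x)
    entries = {key: int(label) for key, label in zip(keys, km.labels_)}
    report = _check_validity(entries, [m.group_key for m in maps], k)
    return ClusterAssignment(
        entries=entries,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        valid=report.valid,
        report=report,
    )


def validate_assignment(assignment: ClusterAssignment) -> ValidityReport:
    """Re-derive the one-map-per-group-per-cluster check from the entries."""
    groups = sorted({g for g, _ in assignment.entries}, key=str)
    k = assignment.centroids.shape[0]
    return _check_validity(assignment.entries, groups, k)


@dataclass
class ConsensusResult:
    """Averaged maps plus the per-group local-state -> consensus-label tables."""

    maps: np.ndarray  # (K, C), rows ordered by descending total |activation|
    relabeling: dict[GroupKey, np.ndarray]  # local state index -> consensus label

    def inverse_relabeling(self, group_key: GroupKey) -> np.ndarray:
        fwd = self.relabeling[group_key]
        inv = np.empty_like(fwd)
        inv[fwd] = np.arange(fwd.size)
        return inv


def consensus_maps(
    maps: Sequence[StateMaps], assignment: ClusterAssignment
) -> ConsensusResult:
    """Average matched maps across groups and build relabeling tables."""
    report = validate_assignment(assignment)
    if not report.valid:
        raise AlignmentError(
            f"cannot build consensus from an invalid assignment: "
            f"{len(report.violations)} violation(s), e.g. {report.violations[0]}"
        )
    k = assignment.centroids.shape[0]
    by_group = {m.group_key: m for m in maps}
    raw = np.stack(
        [
            np.mean(
                [
                    by_group[g].maps[by_group[g].state_ids.index(s)]
                    for (g, s), cl in assignment.entries.items()
                    if cl == cluster
                ],
                axis=0,
            )
            for cluster in range(k)
        ]
    )
    order = np.argsort(-np.abs(raw).sum(axis=1), kind="stable")
    consensus = raw[order]
    cluster_to_label = np.empty(k, dtype=int)
    cluster_to_label[order] = np.arange(k)
    relabeling = {}
    for m in maps:
        table = np.empty(len(m.state_ids), dtype=int)
        for i, s in enumerate(m.state_ids):
            table[i] = cluster_to_label[assignment.entries[(m.group_key, s)]]
        relabeling[m.group_key] = table
    return ConsensusResult(maps=consensus, relabeling=relabeling)


def save_alignment(
    result: ConsensusResult, assignment: ClusterAssignment, out_dir: str | Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    k, c = result.maps.shape
    pd.DataFrame(
        result.maps.T,
        index=[f"ch_{i}" for i in range(c)],
        columns=[f"state_{s + 1}" for s in range(k)],
    ).to_csv(out_dir / "consensus_maps.csv")
    (out_dir / "relabeling.json").write_text(
        json.dumps(
            {"|".join(g): table.tolist() for g, table in result.relabeling.items()}
        )
    )
    (out_dir / "validity_report.json").write_text(
        json.dumps(
            {
                "valid": assignment.valid,
                "inertia": assignment.inertia,
                "violations": [
                    {"cluster": cl, "group": "|".join(g), "count": n}
                    for cl, g, n in assignment.report.violations
                ],
            }
        )
    )
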