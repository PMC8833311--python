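"""Per-subject temporal metrics of brain-state sequences.

From a subject's window-label sequence (states 1..k) this module computes
the four standard occupancy metrics:

* **dwell time** — mean length (in windows) of uninterrupted runs of a state;
* **fraction time** — percentage of windows assigned to a state;
* **transition counts** — number of switches between each unordered state
  pair (direction ignored);
* **occurrence rate** — proportion of subjects who enter a state at all.

Group comparisons of state-wise metrics use only the subjects who actually
visited the state (:func:`visitors_filter`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "DynamicsMetrics",
    "run_lengths",
    "dwell_time",
    "fraction_time",
    "transition_counts",
    "occurrence_rate",
    "visitors_filter",
    "compute_dynamics",
    "dynamics_table",
]


@dataclass
class DynamicsMetrics:
    subject_id: str
    n_windows: int
    dwell: dict[int, float]  # state -> mean run length (visited states only)
    fraction: dict[int, float]  # state -> percent of windows (all states)
    transitions: dict[tuple[int, int], int]  # unordered pair -> count
    visited: set[int]

    @property
    def total_transitions(self) -> int:
        return int(sum(self.transitions.values()))


def run_lengths(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of a label sequence as (state, length) in order."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]


def dwell_time(labels: np.ndarray, state: int) -> float:
    """Mean length of the maximal runs of ``state``; NaN if never visited."""
    runs = [length for s, length in run_lengths(labels) if s == state]
    if not runs:
        return float("nan")
    return float(np.mean(runs))


def fraction_time(labels: np.ndarray, state: int) -> float:
    """Percentage of windows spent in ``state``."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    return 100.0 * float(np.mean(labels == state))


def transition_counts(labels: np.ndarray, k: int | None = None) -> dict[tuple[int, int], int]:
    """Counts of switches per unordered state pair (direction ignored).

    With ``k`` given, all pairs over states 1..k appear (zero-filled);
    otherwise only pairs over states present in the sequence.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    states = range(1, k + 1) if k is not None else sorted(np.unique(labels))
    counts = {tuple(sorted(p)): 0 for p in combinations(states, 2)}
    a, b = labels[:-1], labels[1:]
    for x, y in zip(a[a != b], b[a != b]):
        counts[tuple(sorted((int(x), int(y))))] += 1
    return counts


def occurrence_rate(
    label_seqs: dict[str, np.ndarray], state: int,
    groups: dict[str, str] | None = None,
) -> tuple[float, dict[str, tuple[int, int]]]:
    """Proportion of subjects entering ``state``, plus per-group raw counts.

    Returns (overall proportion, {group: (n_visiting, n_total)}).  With no
    group map all subjects fall in group "all".
    """
    if not label_seqs:
        raise ValueError("need at least one subject")
    per_group: dict[str, list[bool]] = {}
    for sid, labels in label_seqs.items():
        g = groups.get(sid, "all") if groups else "all"
        per_group.setdefault(g, []).append(bool(np.any(np.asarray(labels) == state)))
    visits = [v for vs in per_group.values() for v in vs]
    counts = {g: (int(sum(vs)), len(vs)) for g, vs in per_group.items()}
    return float(np.mean(visits)), counts


def visitors_filter(metrics: list[DynamicsMetrics], state: int) -> list[DynamicsMetrics]:
    """Subjects who entered ``state``; empty result signals 'skip', not error."""
    return [m for m in metrics if state in m.visited]


def compute_dynamics(subject_id: str, labels: np.ndarray, k: int) -> DynamicsMetrics:
    """All per-subject metrics for a window-label sequence over states 1..k."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError("labels must lie in 1..k")
    visited = set(int(s) for s in np.unique(labels))
    dwell = {s: dwell_time(labels, s) for s in visited}
    fraction = {s: fraction_time(labels, s) for s in range(1, k + 1)}
    return DynamicsMetrics(
        subject_id=subject_id,
        n_windows=int(labels.size),
        dwell=dwell,
        fraction=fraction,
        transitions=transition_counts(labels, k=k),
        visited=visited,
    )


def dynamics_table(metrics: list[DynamicsMetrics], k: int) -> pd.DataFrame:
    """Long-format table: one row per subject x state plus subject x pair."""
    rows = []
    for m in metrics:
        for s in range(1, k + 1):
            rows.append({
                "subject_id": m.subject_id, "unit": f"state{s}",
                "dwell": m.dwell.get(s, np.nan),
                "fraction": m.fraction[s],
                "visited": s in m.visited,
                "transitions": np.nan,
            })
        for (a, b), c in m.transitions.items():
            rows.append({
                "subject_id": m.subject_id, "unit": f"pair{a}-{b}",
                "dwell": np.nan, "fraction": np.nan, "visited": np.nan,
                "transitions": c,
            })
    return pd.DataFrame(rows)
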