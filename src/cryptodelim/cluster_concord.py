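"""Cluster-label alignment, hard assignment, and cross-marker concordance.

Bayesian clustering runs label clusters arbitrarily, so replicate runs (and
runs on different marker sets) must be aligned before comparison.  Replicate
alignment maximises the summed column-wise similarity of the q matrices via
optimal one-to-one matching; cross-marker concordance maximises the summed
matched cell counts of the confusion table the same way.  Both use the
Hungarian algorithm, which is exact and deterministic for the small K used
here — a replacement for greedy label-switching heuristics.

Individuals are assigned to a cluster when their membership coefficient
strictly exceeds the threshold (default q > 0.5), otherwise they are
UNDEFINED.  UNDEFINED is never matched, and UNDEFINED–UNDEFINED agreements
do not count as concordant; the concordance denominator nevertheless
includes all individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geno_io import (
    UNDEFINED,
    ClusterAssignment,
    MembershipMatrix,
    ValidationError,
)

__all__ = [
    "ConfusionTable",
    "LabelMatching",
    "align_replicate_runs",
    "assign_clusters",
    "cross_tabulate",
    "concordance",
]


@dataclass
class ConfusionTable:
    """Cross-tabulation of two hard assignments over the same individuals."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # (n_rows, n_cols) non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("confusion table shape mismatch")
        if np.any(self.counts < 0):
            raise ValidationError("confusion table counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_margins(self) -> dict[str, int]:
        return dict(zip(self.row_labels, self.counts.sum(axis=1).tolist()))

    def col_margins(self) -> dict[str, int]:
        return dict(zip(self.col_labels, self.counts.sum(axis=0).tolist()))

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)
        df["Total"] = df.sum(axis=1)
        df.loc["Total"] = df.sum(axis=0)
        return df


@dataclass
class LabelMatching:
    """One-to-one matching between the two assignments' defined clusters."""

    pairs: list[tuple[str, str]]
    objective: int  # summed counts of the matched cells


def align_replicate_runs(runs: list[MembershipMatrix]) -> MembershipMatrix:
    """Align replicate q matrices to the first run and average them.

    Columns of runs 2..R are permuted to maximise the summed dot product
    with the corresponding columns of run 1 (optimal one-to-one matching on
    the K x K similarity matrix of q-vector dot products); the result is the
    element-wise mean of the aligned runs, renormalised so rows sum to 1.
    """
    if not runs:
        raise ValidationError("align_replicate_runs: no runs given")
    ref = runs[0]
    if len(runs) == 1:
        return ref
    aligned = [ref.q]
    for run in runs[1:]:
        if run.individuals != ref.individuals:
            raise ValidationError(
                f"run {run.run_id!r}: individual set differs from {ref.run_id!r}"
            )
        if run.K != ref.K:
            raise ValidationError(f"run {run.run_id!r}: K differs from {ref.run_id!r}")
        similarity = ref.q.T @ run.q  # (K, K) dot products of q columns
        rows, cols = linear_sum_assignment(-similarity)
        perm = np.empty(ref.K, dtype=int)
        perm[rows] = cols
        aligned.append(run.q[:, perm])
    mean_q = np.mean(aligned, axis=0)
    mean_q = mean_q / mean_q.sum(axis=1, keepdims=True)
    return MembershipMatrix(f"mean_of_{len(runs)}", list(ref.individuals), mean_q)


def assign_clusters(
    m: MembershipMatrix,
    threshold: float = 0.5,
    cluster_labels: list[str] | None = None,
) -> ClusterAssignment:
    """Assign each individual to its best cluster when max q strictly exceeds
    ``threshold``; ties at the threshold are UNDEFINED."""
    if not 0.5 <= threshold < 1:
        raise ValidationError(f"threshold must lie in [0.5, 1), got {threshold}")
    labels = cluster_labels or [f"K{k + 1}" for k in range(m.K)]
    if len(labels) != m.K:
        raise ValidationError("cluster_labels length must equal K")
    best = np.argmax(m.q, axis=1)
    assignments = {
        ind: labels[b] if m.q[i, b] > threshold else UNDEFINED
        for i, (ind, b) in enumerate(zip(m.individuals, best))
    }
    return ClusterAssignment(assignments, threshold)


def cross_tabulate(a: ClusterAssignment, b: ClusterAssignment) -> ConfusionTable:
    """Count individuals by their (assignment A, assignment B) cluster pair."""
    if set(a.assignments) != set(b.assignments):
        only = set(a.assignments) ^ set(b.assignments)
        raise ValidationError(
            f"assignments cover different individuals ({len(only)} unshared)"
        )
    row_labels = sorted({c for c in a.assignments.values() if c != UNDEFINED})
    col_labels = sorted({c for c in b.assignments.values() if c != UNDEFINED})
    row_labels.append(UNDEFINED)
    col_labels.append(UNDEFINED)
    ri = {lab: i for i, lab in enumerate(row_labels)}
    ci = {lab: i for i, lab in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    for ind, ca in a.assignments.items():
        counts[ri[ca], ci[b.assignments[ind]]] += 1
    return ConfusionTable(row_labels, col_labels, counts)


def concordance(t: ConfusionTable) -> dict:
    """Optimal one-to-one matching of defined clusters and the concordant count.

    The matching maximises the summed matched-cell counts over the defined
    clusters (Hungarian algorithm; ties resolved deterministically by
    lexicographic label order since labels are sorted).  UNDEFINED cells are
    never matched nor counted; the fraction is taken over all individuals.
    """
    rows = [i for i, lab in enumerate(t.row_labels) if lab != UNDEFINED]
    cols = [j for j, lab in enumerate(t.col_labels) if lab != UNDEFINED]
    if not rows or not cols:
        raise ValidationError("concordance: need at least one defined cluster per axis")
    sub = t.counts[np.ix_(rows, cols)]
    ri, ci = linear_sum_assignment(-sub)
    pairs = sorted(
        (t.row_labels[rows[i]], t.col_labels[cols[j]]) for i, j in zip(ri, ci)
    )
    n_concordant = int(sub[ri, ci].sum())
    return {
        "matching": LabelMatching(pairs, n_concordant),
        "n_concordant": n_concordant,
        "fraction": n_concordant / t.total if t.total else float("nan"),
    }
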