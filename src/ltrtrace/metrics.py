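"""External clustering-evaluation metrics: purity, Rand index, pair-counting F-beta.

All three compare a predicted partition against ground-truth labels through
the contingency table and are invariant to permutation of predicted labels.
F-beta is computed on element pairs (the natural companion of the Rand
index): a pair is a true positive when both partitions co-cluster it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

__all__ = ["ContingencyTable", "purity", "rand_index", "f_beta", "evaluate_labels"]


@dataclass
class ContingencyTable:
    """n[i, j] = number of elements with true label i and predicted label j."""

    counts: np.ndarray
    true_labels: list
    pred_labels: list

    @classmethod
    def from_labels(
        cls, truth: Sequence[Hashable], prediction: Sequence[Hashable]
    ) -> "ContingencyTable":
        if len(truth) != len(prediction):
            raise ValueError("truth and prediction must have equal length")
        ti = sorted(set(truth), key=str)
        pi = sorted(set(prediction), key=str)
        t_idx = {lab: i for i, lab in enumerate(ti)}
        p_idx = {lab: j for j, lab in enumerate(pi)}
        counts = np.zeros((len(ti), len(pi)), dtype=np.int64)
        for t, p in zip(truth, prediction):
            counts[t_idx[t], p_idx[p]] += 1
        return cls(counts=counts, true_labels=ti, pred_labels=pi)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _pair_counts(table: ContingencyTable) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) over element pairs."""

    def c2(x: np.ndarray) -> int:
        return int((x * (x - 1) // 2).sum())

    n = table.counts
    tp = c2(n)
    fp = c2(n.sum(axis=0)) - tp
    fn = c2(n.sum(axis=1)) - tp
    total = table.n * (table.n - 1) // 2
    tn = total - tp - fp - fn
    return tp, fp, fn, tn


def purity(table: ContingencyTable) -> float:
    """Fraction of elements belonging to the majority true class of their
    predicted cluster: (1/N) * sum_j max_i n_ij."""
    if table.n < 1:
        raise ValueError("empty contingency table")
    return float(table.counts.max(axis=0).sum() / table.n)


def rand_index(table: ContingencyTable) -> float:
    """(TP + TN) / C(N, 2) over element pairs."""
    if table.n < 2:
        raise ValueError("Rand index needs at least 2 elements")
    tp, fp, fn, tn = _pair_counts(table)
    return (tp + tn) / (tp + fp + fn + tn)


def f_beta(table: ContingencyTable, beta: float = 1.0) -> float:
    """Pair-counting F-beta: (1+b^2)PR / (b^2 P + R); 0 when TP = 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    tp, fp, fn, _ = _pair_counts(table)
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return (1 + beta**2) * p * r / (beta**2 * p + r)


def evaluate_labels(
    truth: Sequence[Hashable], prediction: Sequence[Hashable], beta: float = 1.0
) -> dict[str, float]:
    """Convenience wrapper: all three metrics from two label vectors."""
    table = ContingencyTable.from_labels(truth, prediction)
    return {
        "purity": purity(table),
        "rand_index": rand_index(table),
        f"f{beta:g}": f_beta(table, beta),
    }
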