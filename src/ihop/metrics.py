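"""Evaluation metrics: micro-F1, shortfall, and average rank.

Micro-F1 pools true/false positive/negative counts over all node-label
pairs.  Shortfall and average rank are cross-dataset consistency measures
computed on a model x dataset micro-F1 grid: shortfall is the mean gap to
the per-dataset best model, average rank the mean of per-dataset descending
ranks (1 = best).  The package bundles the published transductive micro-F1
grid of 11 collective-classification models on 11 standard benchmark
networks (citation, social, biological, product and movie graphs) so those
aggregate measures can be recomputed exactly from printed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "micro_f1",
    "ResultsTable",
    "shortfall",
    "average_rank",
    "wins",
    "load_benchmark_table",
    "round_half_up",
]


def micro_f1(pred: np.ndarray, truth: np.ndarray) -> float:
    """Micro-averaged F1 from globally pooled counts: 2TP/(2TP+FP+FN).

    Inputs are binary matrices of identical shape (multi-class inputs
    one-hot).  Returns 1.0 when both prediction and truth contain no
    positives at all.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(truth, (0, 1)).all()):
        raise ValueError("micro_f1 expects binary (0/1) matrices")
    tp = float(np.sum((pred == 1) & (truth == 1)))
    fp = float(np.sum((pred == 1) & (truth == 0)))
    fn = float(np.sum((pred == 0) & (truth == 1)))
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2 * tp / denom


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ResultsTable:
    """A complete model x dataset micro-F1 grid on the percent scale."""

    models: list[str]
    datasets: list[str]
    scores: np.ndarray  # shape (n_models, n_datasets), values in [0, 100]

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.models), len(self.datasets)):
            raise ValueError("scores shape does not match model/dataset lists")
        if np.isnan(self.scores).any():
            raise ValueError("results grid has missing cells")
        if ((self.scores < 0) | (self.scores > 100)).any():
            raise ValueError("micro-F1 scores must lie in [0, 100]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResultsTable":
        return cls(models=list(df.index), datasets=list(df.columns),
                   scores=df.to_numpy(dtype=np.float64))

    @classmethod
    def from_csv(cls, path) -> "ResultsTable":
        return cls.from_frame(pd.read_csv(path, index_col=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.models,
                            columns=self.datasets)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def shortfall(table: ResultsTable) -> pd.Series:
    """Mean per-dataset gap to the best model (percentage points).

    For each dataset the best model contributes exactly 0; adding a constant
    to an entire dataset column leaves every shortfall unchanged.  Returned
    unrounded; use :func:`round_half_up` to compare with printed tables.
    """
    best = table.scores.max(axis=0)
    vals = (best[None, :] - table.scores).mean(axis=1)
    return pd.Series(vals, index=table.models, name="shortfall")


def average_rank(table: ResultsTable, tie_policy: str = "min") -> pd.Series:
    """Mean per-dataset rank by descending score (1 = best).

    ``tie_policy='min'`` gives competition ranking (ties share the best
    position); ``'mean'`` averages tied positions.
    """
    if tie_policy not in ("min", "mean"):
        raise ValueError("tie_policy must be 'min' or 'mean'")
    method = {"min": "min", "mean": "average"}[tie_policy]
    ranks = np.column_stack([
        rankdata(-table.scores[:, j], method=method)
        for j in range(len(table.datasets))
    ])
    return pd.Series(ranks.mean(axis=1), index=table.models, name="rank")


def wins(table: ResultsTable) -> pd.Series:
    """Number of datasets on which each model attains the column maximum."""
    best = table.scores.max(axis=0)
    return pd.Series((table.scores == best[None, :]).sum(axis=1),
                     index=table.models, name="wins")


def load_benchmark_table() -> ResultsTable:
    """The bundled 11-model x 11-dataset transductive micro-F1 grid."""
    ref = resources.files("ihop").joinpath("data/benchmark_micro_f1.csv")
    with resources.as_file(ref) as path:
        return ResultsTable.from_csv(path)
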