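"""Otolith age-reading bias and error.

True ages become recorded "otolith ages" through a row-stochastic
misclassification matrix ``P[read = r | true = a]`` over age groups
``0..age_cap``.  The default matrix is a parametric stand-in calibrated to
an aggregate reading accuracy (the probability that the read age equals the
true age): every row has its diagonal set exactly to the target accuracy and
spreads the remaining mass over neighbouring ages with geometric decay,
optionally skewed to express systematic over-/under-ageing.  Because every
diagonal equals the target, the weight-averaged accuracy equals the target
for any age-weight vector.  A user-supplied matrix (e.g. from a reference
ageing study) is accepted anywhere a :class:`ReadingModel` is.

A second-reader precision check re-reads a fraction of the sub-sample with
independent randomness and reports the standard fisheries ageing-precision
metric: the per-fish coefficient of variation of the paired reads, averaged
within first-read age group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def calibrate_bias_matrix(
    age_cap: int = 12,
    target_accuracy: float = 0.61,
    spread: float = 0.35,
    asymmetry: float = 1.0,
    age_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Build the default misclassification matrix.

    ``age_weights`` are the true-age proportions of the population the
    aggregate accuracy is calibrated over; because every diagonal is set to
    the target exactly, the weighted aggregate equals the target for any
    weight vector, and the weights only enter a consistency check here.

    Row ``a`` has ``P[a|a] = target_accuracy``; the off-diagonal mass
    ``1 - target_accuracy`` is distributed over ages ``r != a``
    proportionally to ``spread**|r-a| * asymmetry**sign(r-a)`` and
    renormalized within the valid age range (edge rows fold the lost mass
    inward without touching the diagonal).

    ``spread = 0`` with ``target_accuracy = 1`` gives the identity (perfect
    reader); ``asymmetry > 1`` biases reads old, ``< 1`` young.
    """
    if not 0 < target_accuracy <= 1:
        raise ValueError("target_accuracy must be in (0, 1]")
    if spread < 0 or (spread == 0 and target_accuracy < 1):
        raise ValueError("off-diagonal mass needs spread > 0 unless target_accuracy == 1")
    if target_accuracy == 1.0 and spread > 0:
        raise ValueError("target_accuracy 1.0 is unreachable with positive spread")
    if age_weights is not None:
        age_weights = np.asarray(age_weights, dtype=float)
        if len(age_weights) != age_cap + 1 or not np.isclose(age_weights.sum(), 1.0):
            raise ValueError("age_weights must cover ages 0..age_cap and sum to 1")
    n = age_cap + 1
    if target_accuracy == 1.0:
        return np.eye(n)
    ages = np.arange(n)
    offset = ages[None, :] - ages[:, None]
    kernel = spread ** np.abs(offset).astype(float) * np.where(
        offset > 0, asymmetry, np.where(offset < 0, 1.0 / asymmetry, 1.0)
    )
    np.fill_diagonal(kernel, 0.0)
    off_mass = kernel / kernel.sum(axis=1, keepdims=True)
    matrix = (1.0 - target_accuracy) * off_mass
    np.fill_diagonal(matrix, target_accuracy)
    return matrix


def _validate_matrix(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("bias matrix must be square")
    if (matrix < 0).any():
        raise ValueError("bias matrix entries must be non-negative")
    if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("bias matrix rows must sum to 1")
    return matrix


@dataclass
class ReadingModel:
    """Age-reading model: misclassification matrix + second-reader protocol."""

    bias_matrix: np.ndarray = None  # type: ignore[assignment]
    target_accuracy: float = 0.61
    spread: float = 0.35
    asymmetry: float = 1.0
    age_cap: int = 12
    second_reader_fraction: float = 0.20

    def __post_init__(self):
        if self.bias_matrix is None:
            self.bias_matrix = calibrate_bias_matrix(
                self.age_cap, self.target_accuracy, self.spread, self.asymmetry
            )
        self.bias_matrix = _validate_matrix(self.bias_matrix)
        self.age_cap = self.bias_matrix.shape[0] - 1

    @classmethod
    def identity(cls, age_cap: int = 12) -> "ReadingModel":
        """Perfect reader: otolith age always equals true age."""
        return cls(bias_matrix=np.eye(age_cap + 1), target_accuracy=1.0, spread=0.0, age_cap=age_cap)

    def accuracy(self, age_weights: np.ndarray | None = None) -> float:
        """Weight-averaged diagonal (aggregate reading accuracy)."""
        diag = np.diag(self.bias_matrix)
        if age_weights is None:
            return float(diag.mean())
        w = np.asarray(age_weights, dtype=float)
        w = w / w.sum()
        return float(w @ diag)


def read_age(true_age, model: ReadingModel, rng: np.random.Generator) -> np.ndarray:
    """Draw otolith ages from the misclassification matrix (vectorized)."""
    true_age = np.atleast_1d(np.asarray(true_age, dtype=int))
    if (true_age < 0).any() or (true_age > model.age_cap).any():
        raise ValueError(f"true ages must lie in [0, {model.age_cap}]")
    cum = np.cumsum(model.bias_matrix, axis=1)
    u = rng.random(len(true_age))
    return (u[:, None] > cum[true_age]).sum(axis=1).astype(int)


def apply_reading(
    records: pd.DataFrame,
    model: ReadingModel,
    rng: np.random.Generator,
    true_col: str = "true_age",
) -> pd.DataFrame:
    """Return a copy of sub-sample records with an ``otolith_age`` column."""
    out = records.copy()
    out["otolith_age"] = read_age(out[true_col].to_numpy(), model, rng)
    return out


def second_reader_check(
    records: pd.DataFrame,
    model: ReadingModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Inter-reader precision check on a fraction of the sub-sample.

    Uniformly selects ``floor(fraction * n)`` records, re-reads their true
    ages with independent randomness, and computes the per-fish CV of the
    two reads, ``sd(reads, ddof=1) / mean(reads)`` (zero when both reads are
    age 0).  Returns a table aggregated by first-reader age:
    ``age, n, mean_cv``.
    """
    if records.empty:
        raise ValueError("sub-sample is empty")
    if "otolith_age" not in records:
        raise ValueError("records need an 'otolith_age' column (run apply_reading first)")
    n_check = int(np.floor(model.second_reader_fraction * len(records)))
    idx = rng.choice(len(records), size=n_check, replace=False)
    first = records["otolith_age"].to_numpy()[idx]
    second = read_age(records["true_age"].to_numpy()[idx], model, rng)
    pair_mean = (first + second) / 2.0
    pair_sd = np.abs(first - second) / np.sqrt(2.0)
    cv = np.divide(pair_sd, pair_mean, out=np.zeros_like(pair_sd, dtype=float), where=pair_mean > 0)
    table = (
        pd.DataFrame({"age": first, "cv": cv})
        .groupby("age")
        .agg(n=("cv", "size"), mean_cv=("cv", "mean"))
        .reset_index()
    )
    return table


def write_bias_matrix(matrix: np.ndarray, path: str | Path, delimiter: str = ",") -> None:
    """Write a bias matrix as delimited text with age labels."""
    n = matrix.shape[0]
    df = pd.DataFrame(matrix, index=range(n), columns=[f"read_{r}" for r in range(n)])
    df.index.name = "true_age"
    df.to_csv(path, sep=delimiter)


def read_bias_matrix(path: str | Path, delimiter: str = ",") -> np.ndarray:
    """Read a bias matrix written by :func:`write_bias_matrix`."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return _validate_matrix(df.to_numpy())
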