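"""Sub-sampling strategy evaluation.

Given an aged sub-sample of a virtual population, this module quantifies how
well the population's trait structure is recovered:

* fit the weighted additive age model (:mod:`surveysub.gam`) with
  size-specific within-site abundance weights;
* repeated-holdout prediction error (default 300 iterations deleting 30% of
  the records at a time), reported as the mean absolute difference between
  the model's discretized age prediction and the fish's true age group (the
  continuous-scale MAE and the signed mean are reported alongside);
* reconstruction of the population age-frequency distribution by predicting
  an age for every measured (stage-2) fish, and the mis-aged fraction — the
  total-variation distance between predicted and true compositions;
* mean and modal size-at-age for age groups 1-3;
* recovery of the spatial pattern in mean size and age over a regular grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binned_statistic_2d

from .designs import SubSample
from .gam import AgeGAM, AgeGAMResults, GamSpec
from .population import VirtualPopulation, discretize_age


def compute_weights(records: pd.DataFrame, stage2_counts: pd.DataFrame) -> np.ndarray:
    """Size-specific within-site abundance weights, rescaled to mean 1.

    The weight of an aged fish is the number of measured fish in its
    (site, 1-cm bin) cell of the stage-2 table, so length intervals that are
    better represented in the catch carry more weight in the model fit.
    """
    merged = records[["site_id", "cm_bin"]].merge(
        stage2_counts, on=["site_id", "cm_bin"], how="left"
    )
    w = merged["count"].to_numpy(dtype=float)
    if np.isnan(w).any():
        bad = records.index[np.isnan(w)].tolist()
        raise ValueError(f"records with no stage-2 (site, cm bin) cell: rows {bad}")
    return w / w.mean()


@dataclass
class PredictionErrorResult:
    """Repeated-holdout prediction error of the age model."""

    mean_error: float
    sd_error: float
    mean_error_continuous: float
    mean_error_signed: float
    n_iterations: int
    holdout_fraction: float
    n_failures: int = 0
    degenerate_sd: bool = False


def cv_prediction_error(
    records: pd.DataFrame,
    weights: np.ndarray,
    spec: GamSpec,
    rng: np.random.Generator,
    n_iterations: int = 300,
    holdout: float = 0.30,
    alphas: tuple[float, ...] | None = None,
    age_cap: int = 12,
) -> PredictionErrorResult:
    """Repeated random holdout: fit on 70%, predict the deleted 30%.

    Per iteration the mean absolute error between the discretized prediction
    and the true age group is recorded; the result carries the mean and s.d.
    over iterations.  Smoothing parameters default to one GCV selection on
    the full sample, reused across iterations.  Iterations whose fit fails
    are skipped and counted.
    """
    records = records.reset_index(drop=True)
    if alphas is None:
        alphas = AgeGAM(records, weights, spec).fit().alphas
    n = len(records)
    n_hold = max(int(round(holdout * n)), 1)
    errors, errors_cont, errors_signed = [], [], []
    failures = 0
    for _ in range(n_iterations):
        hold = rng.choice(n, size=n_hold, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[hold] = True
        try:
            res = AgeGAM(records[~mask], weights[~mask], spec).fit(alphas=alphas)
            pred = res.predict(records[mask])
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        truth = records.loc[mask, "true_age"].to_numpy()
        pred_group = discretize_age(pred, age_cap)
        errors.append(float(np.mean(np.abs(pred_group - truth))))
        errors_cont.append(float(np.mean(np.abs(pred - truth))))
        errors_signed.append(float(np.mean(pred - truth)))
    if not errors:
        raise RuntimeError("every holdout iteration failed to fit")
    degenerate = len(errors) < 2
    return PredictionErrorResult(
        mean_error=float(np.mean(errors)),
        sd_error=0.0 if degenerate else float(np.std(errors, ddof=1)),
        mean_error_continuous=float(np.mean(errors_cont)),
        mean_error_signed=float(np.mean(errors_signed)),
        n_iterations=n_iterations,
        holdout_fraction=holdout,
        n_failures=failures,
        degenerate_sd=degenerate,
    )


def predict_age_frequency(
    fit: AgeGAMResults,
    stage2_fish: pd.DataFrame,
    age_cap: int = 12,
) -> pd.Series:
    """Predict an age group for every measured fish and tabulate counts.

    ``stage2_fish`` needs ``length_mm, sex, longitude, latitude``.  The
    prediction is discretized with the population's rounding rule, so the
    counts total the number of stage-2 fish.
    """
    pred = fit.predict(stage2_fish)
    groups = discretize_age(pred, age_cap)
    counts = np.bincount(groups, minlength=age_cap + 1)
    return pd.Series(counts, index=range(age_cap + 1), name="count")


def misaged_fraction(predicted: pd.Series | np.ndarray, truth: pd.Series | np.ndarray) -> float:
    """Total-variation distance between two age compositions with equal totals."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if len(p) < len(t):
        p = np.pad(p, (0, len(t) - len(p)))
    elif len(t) < len(p):
        t = np.pad(t, (0, len(p) - len(t)))
    if not np.isclose(p.sum(), t.sum()):
        raise ValueError(f"totals differ: {p.sum()} vs {t.sum()}")
    return float(0.5 * np.abs(p - t).sum() / t.sum())


def size_at_age(
    records: pd.DataFrame,
    ages: tuple[int, ...] = (1, 2, 3),
    age_col: str = "otolith_age",
) -> pd.DataFrame:
    """Mean and modal size (cm) per age group with standard errors.

    Modal size is the most frequent 1-cm bin; ties break toward the
    smaller bin.  Absent age groups are reported with ``n = 0``.
    """
    rows = []
    for a in ages:
        sub = records[records[age_col] == a]
        if len(sub) == 0:
            rows.append({"age": a, "n": 0, "mean_length": np.nan, "se_length": np.nan, "modal_bin": np.nan})
            continue
        lengths_cm = sub["length_mm"].to_numpy() / 10.0
        bins = sub["cm_bin"].to_numpy()
        counts = np.bincount(bins)
        modal = int(np.flatnonzero(counts == counts.max())[0])
        se = float(np.std(lengths_cm, ddof=1) / np.sqrt(len(sub))) if len(sub) > 1 else 0.0
        rows.append(
            {
                "age": a,
                "n": len(sub),
                "mean_length": float(lengths_cm.mean()),
                "se_length": se,
                "modal_bin": modal,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SpatialPattern:
    """Gridded cell means of a per-fish value with a minimum-count mask."""

    cell_means: np.ndarray
    counts: np.ndarray
    lon_edges: np.ndarray
    lat_edges: np.ndarray
    min_fish: int

    @property
    def mask(self) -> np.ndarray:
        return self.counts >= self.min_fish


def spatial_pattern(
    data: pd.DataFrame,
    value_col: str,
    bounds: tuple[float, float, float, float] | None = None,
    n_cells: int = 20,
    min_fish: int = 5,
) -> SpatialPattern:
    """Cell-mean map of a fish-level value over a regular lon/lat grid."""
    lon = data["longitude"].to_numpy()
    lat = data["latitude"].to_numpy()
    vals = data[value_col].to_numpy(dtype=float)
    if bounds is None:
        bounds = (lon.min(), lon.max(), lat.min(), lat.max())
    lon_edges = np.linspace(bounds[0], bounds[1], n_cells + 1)
    lat_edges = np.linspace(bounds[2], bounds[3], n_cells + 1)
    means, _, _, _ = binned_statistic_2d(lon, lat, vals, statistic="mean", bins=[lon_edges, lat_edges])
    counts, _, _, _ = binned_statistic_2d(lon, lat, vals, statistic="count", bins=[lon_edges, lat_edges])
    return SpatialPattern(means, counts.astype(int), lon_edges, lat_edges, min_fish)


def compare_patterns(a: SpatialPattern, b: SpatialPattern) -> dict:
    """Map agreement over the shared unmasked cells.

    Returns correlation (NaN + flag when either map is constant), RMSE and
    max absolute cell difference.
    """
    shared = a.mask & b.mask
    if not shared.any():
        raise ValueError("patterns share no unmasked cells")
    va, vb = a.cell_means[shared], b.cell_means[shared]
    diff = va - vb
    degenerate = np.std(va) == 0 or np.std(vb) == 0
    corr = np.nan if degenerate else float(np.corrcoef(va, vb)[0, 1])
    return {
        "correlation": corr,
        "degenerate": bool(degenerate),
        "rmse": float(np.sqrt(np.mean(diff**2))),
        "max_abs_diff": float(np.abs(diff).max()),
        "n_shared_cells": int(shared.sum()),
    }


@dataclass
class EvaluationReport:
    """Everything the evaluation computes for one design's sub-sample."""

    design_kind: str
    fit: AgeGAMResults
    prediction_error: PredictionErrorResult
    true_age_frequency: pd.Series
    predicted_age_frequency: pd.Series
    misaged: float
    size_at_age_sample: pd.DataFrame
    size_at_age_population: pd.DataFrame
    spatial_metrics: dict = field(default_factory=dict)

    def to_text(self) -> str:
        parts = [
            f"design: {self.design_kind}",
            self.fit.summary(),
            (
                f"holdout MAE {self.prediction_error.mean_error:.3f} "
                f"(sd {self.prediction_error.sd_error:.3f}, "
                f"continuous {self.prediction_error.mean_error_continuous:.3f}, "
                f"signed {self.prediction_error.mean_error_signed:+.3f})"
            ),
            f"mis-aged fraction {self.misaged:.4f}",
            "size at age (sample):",
            self.size_at_age_sample.to_string(index=False),
        ]
        if self.spatial_metrics:
            parts.append(f"spatial recovery: {self.spatial_metrics}")
        return "\n".join(parts)


def evaluate_design(
    pop: VirtualPopulation,
    subsample: SubSample,
    spec: GamSpec,
    rng: np.random.Generator,
    n_iterations: int = 300,
    holdout: float = 0.30,
    age_cap: int = 12,
    map_cells: int = 10,
    map_min_fish: int = 3,
) -> EvaluationReport:
    """Run the full evaluation for one aged sub-sample.

    ``subsample.records`` must carry ``otolith_age`` (see
    :func:`surveysub.ageing.apply_reading`).
    """
    records = subsample.records.reset_index(drop=True)
    stage2 = pop.stage2_counts()
    weights = compute_weights(records, stage2)
    fit = AgeGAM(records, weights, spec).fit()
    pe = cv_prediction_error(
        records, weights, spec, rng, n_iterations=n_iterations, holdout=holdout,
        alphas=fit.alphas, age_cap=age_cap,
    )
    truth = np.bincount(pop.fish["true_age"].to_numpy(), minlength=age_cap + 1)
    truth = pd.Series(truth, index=range(age_cap + 1), name="count")
    predicted = predict_age_frequency(fit, pop.fish, age_cap=age_cap)
    mis = misaged_fraction(predicted, truth)
    saa_sample = size_at_age(records, age_col="otolith_age")
    saa_pop = size_at_age(pop.fish, age_col="true_age")

    bounds = (
        pop.fish["longitude"].min(),
        pop.fish["longitude"].max(),
        pop.fish["latitude"].min(),
        pop.fish["latitude"].max(),
    )
    metrics = {}
    for value, col in (("age", None), ("size", "length_mm")):
        if value == "age":
            pop_map = spatial_pattern(
                pop.fish.assign(_v=pop.fish["true_age_cont"]), "_v", bounds, map_cells, min_fish=5
            )
            sub_map = spatial_pattern(
                records.assign(_v=records["otolith_age"]), "_v", bounds, map_cells, map_min_fish
            )
        else:
            pop_map = spatial_pattern(pop.fish, col, bounds, map_cells, min_fish=5)
            sub_map = spatial_pattern(records, col, bounds, map_cells, map_min_fish)
        try:
            metrics[value] = compare_patterns(pop_map, sub_map)
        except ValueError:
            metrics[value] = {"error": "no shared unmasked cells"}
    return EvaluationReport(
        design_kind=subsample.design.kind,
        fit=fit,
        prediction_error=pe,
        true_age_frequency=truth,
        predicted_age_frequency=predicted,
        misaged=mis,
        size_at_age_sample=saa_sample,
        size_at_age_population=saa_pop,
        spatial_metrics=metrics,
    )
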