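"""Factorial sensitivity analysis of error sources.

The full 2 x 2 x 2 grid crosses, for each sub-sampling design and replicate:

* ``autocorr`` — whether the virtual population carries the spatially
  autocorrelated site error (off keeps the nugget as independent site noise
  by default, isolating the *correlation* rather than the variance; an
  alternative mode removes site error entirely);
* ``reading_error`` — whether otolith ages pass through the calibrated
  misclassification matrix or equal the true ages (identity matrix);
* ``spatial_term`` — whether the evaluation model includes the bivariate
  spatial smooth.

Each cell records explained variance, holdout prediction error, the
mis-aged fraction of the reconstructed age composition, and the
size-at-age deltas against the population.  Marginal on-minus-off
contrasts per factor attribute the error contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from . import designs as designs_mod
from .ageing import ReadingModel, apply_reading
from .evaluation import (
    compute_weights,
    cv_prediction_error,
    misaged_fraction,
    predict_age_frequency,
    size_at_age,
)
from .gam import AgeGAM, GamSpec
from .population import ScenarioSpec, build_population, default_spatial_model
from .spatial import SpatialErrorModel

FACTORS = ("autocorr", "reading_error", "spatial_term")
OUTPUTS = (
    "pct_variance_explained",
    "mean_error",
    "sd_error",
    "misaged_fraction",
    "saa_delta_age1",
    "saa_delta_age2",
    "saa_delta_age3",
)


@dataclass
class SensitivityReport:
    """Long-format grid results plus the factor attribution table."""

    cells: pd.DataFrame
    attribution: pd.DataFrame
    interaction_remainder: pd.DataFrame
    provenance: dict

    def complete(self) -> bool:
        expected = 8 * self.cells["design"].nunique() * self.cells["replicate"].nunique()
        return len(self.cells) == expected


def _no_autocorr_model(model: SpatialErrorModel, mode: str) -> SpatialErrorModel:
    if mode == "decorrelate":
        return dc_replace(model, sill=model.nugget)
    if mode == "none":
        return dc_replace(model, sill=0.0, nugget=0.0)
    raise ValueError("autocorr_off_mode must be 'decorrelate' or 'none'")


def _draw_subsample(pop, preselected, design_kind, design_config, rng):
    if design_kind == "random":
        cfg = dc_replace(design_config, kind="random")
        return designs_mod.random_subsample(pop, preselected, cfg, rng)
    if design_kind == "length_stratified":
        cfg = dc_replace(design_config, kind="length_stratified")
        return designs_mod.stratified_subsample(pop, preselected, cfg, rng)
    if design_kind == "census":
        return designs_mod.census_subsample(pop, preselected)
    raise ValueError(f"unsupported design kind {design_kind!r}")


def _evaluate_cell(pop, records, spec, rng, n_cv_iterations, age_cap):
    stage2 = pop.stage2_counts()
    weights = compute_weights(records, stage2)
    fit = AgeGAM(records, weights, spec).fit()
    pe = cv_prediction_error(
        records, weights, spec, rng, n_iterations=n_cv_iterations, alphas=fit.alphas, age_cap=age_cap
    )
    truth = np.bincount(pop.fish["true_age"].to_numpy(), minlength=age_cap + 1)
    predicted = predict_age_frequency(fit, pop.fish, age_cap=age_cap)
    mis = misaged_fraction(predicted.to_numpy(), truth)
    saa_s = size_at_age(records, age_col="otolith_age").set_index("age")["mean_length"]
    saa_p = size_at_age(pop.fish, age_col="true_age").set_index("age")["mean_length"]
    delta = saa_s - saa_p
    return {
        "pct_variance_explained": fit.pct_variance_explained,
        "mean_error": pe.mean_error,
        "sd_error": pe.sd_error,
        "misaged_fraction": mis,
        "saa_delta_age1": float(delta.get(1, np.nan)),
        "saa_delta_age2": float(delta.get(2, np.nan)),
        "saa_delta_age3": float(delta.get(3, np.nan)),
        "n_records": len(records),
    }


def run_sensitivity_grid(
    hauls: pd.DataFrame,
    lengths: pd.DataFrame,
    otoliths: pd.DataFrame | None = None,
    scenario: str = "warm",
    design_kinds: tuple[str, ...] = ("random", "length_stratified"),
    design_config: designs_mod.DesignConfig | None = None,
    reading_model: ReadingModel | None = None,
    gam_spec: GamSpec | None = None,
    spatial_model: SpatialErrorModel | None = None,
    n_replicates: int = 20,
    n_cv_iterations: int = 30,
    seed: int = 0,
    autocorr_off_mode: str = "decorrelate",
    age_cap: int = 12,
) -> SensitivityReport:
    """Run the full 2x2x2 factor grid across designs and replicates.

    Populations are rebuilt per replicate and autocorrelation arm with
    replicate-specific seeds; the same site preselection is shared by all
    cells of a replicate.  A cell whose pipeline fails is recorded with the
    failure rather than silently dropped.
    """
    design_config = design_config or designs_mod.DesignConfig()
    reading_model = reading_model or ReadingModel(age_cap=age_cap)
    gam_spec = gam_spec or GamSpec()
    spec = ScenarioSpec(scenario)
    identity = ReadingModel.identity(age_cap)
    master = np.random.default_rng(seed)

    from .geometry import build_site_table

    base_model = spatial_model or default_spatial_model(build_site_table(hauls))
    off_model = _no_autocorr_model(base_model, autocorr_off_mode)

    rows = []
    failures = []
    for rep in range(n_replicates):
        rep_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        pops = {}
        for autocorr in (True, False):
            pops[autocorr] = build_population(
                hauls, lengths, spec,
                spatial_model=base_model if autocorr else off_model,
                seed=np.random.default_rng(rep_seed), otoliths=otoliths,
            )
        preselected = designs_mod.select_age_sites(
            pops[True].sites, design_config.site_fraction, rng
        )
        for design_kind in design_kinds:
            for autocorr in (True, False):
                pop = pops[autocorr]
                sub = _draw_subsample(pop, preselected, design_kind, design_config, rng)
                for reading in (True, False):
                    model = reading_model if reading else identity
                    records = apply_reading(sub.records, model, rng)
                    for spatial_term in (True, False):
                        cell_spec = dc_replace(gam_spec, include_spatial=spatial_term)
                        cell_id = {
                            "design": design_kind,
                            "replicate": rep,
                            "autocorr": autocorr,
                            "reading_error": reading,
                            "spatial_term": spatial_term,
                        }
                        try:
                            out = _evaluate_cell(
                                pop, records, cell_spec, rng, n_cv_iterations, age_cap
                            )
                        except Exception as exc:  # noqa: BLE001 - reported, not hidden
                            failures.append({**cell_id, "error": repr(exc)})
                            continue
                        rows.append({**cell_id, **out})
    cells = pd.DataFrame(rows)
    if failures:
        raise RuntimeError(f"{len(failures)} sensitivity cells failed: {failures[:3]}")
    attribution, remainder = attribute_errors_from_cells(cells)
    return SensitivityReport(
        cells=cells,
        attribution=attribution,
        interaction_remainder=remainder,
        provenance={
            "scenario": scenario,
            "n_replicates": n_replicates,
            "seed": seed,
            "autocorr_off_mode": autocorr_off_mode,
        },
    )


def attribute_errors_from_cells(cells: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marginal on-minus-off contrast per factor, design and output.

    The contrast is computed within each replicate (mean over the four cells
    with the factor on, minus the four with it off) and then averaged, so the
    reported s.d. is the replicate-to-replicate dispersion.  The interaction
    remainder compares the all-on cell against the all-off cell plus the sum
    of the marginal contrasts.
    """
    required = set(FACTORS) | {"design", "replicate"}
    if not required <= set(cells.columns):
        raise ValueError(f"grid is missing columns {sorted(required - set(cells.columns))}")
    per_design = cells.groupby("design")
    for design, grp in per_design:
        per_rep = grp.groupby("replicate").size()
        if (per_rep != 8).any():
            raise ValueError(f"incomplete factor grid for design {design!r}")
    outputs = [c for c in OUTPUTS if c in cells.columns]
    attr_rows = []
    rem_rows = []
    for design, grp in per_design:
        for factor in FACTORS:
            contrasts = (
                grp.groupby(["replicate", factor])[outputs]
                .mean()
                .unstack(factor)
            )
            for out in outputs:
                diff = contrasts[(out, True)] - contrasts[(out, False)]
                attr_rows.append(
                    {
                        "design": design,
                        "factor": factor,
                        "output": out,
                        "contrast": float(diff.mean()),
                        "sd": float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
                    }
                )
        all_on = grp[grp[list(FACTORS)].all(axis=1)]
        all_off = grp[~grp[list(FACTORS)].any(axis=1)]
        for out in outputs:
            total_contrast = sum(
                r["contrast"] for r in attr_rows if r["design"] == design and r["output"] == out
            )
            rem_rows.append(
                {
                    "design": design,
                    "output": out,
                    "all_on": float(all_on[out].mean()),
                    "all_off": float(all_off[out].mean()),
                    "remainder": float(all_on[out].mean() - all_off[out].mean() - total_contrast),
                }
            )
    return pd.DataFrame(attr_rows), pd.DataFrame(rem_rows)


def attribute_errors(report: SensitivityReport) -> pd.DataFrame:
    """Recompute the attribution table from a report's cells."""
    attribution, _ = attribute_errors_from_cells(report.cells)
    return attribution
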