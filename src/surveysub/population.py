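"""Virtual population construction.

A virtual population is built by resampling survey tables so that each
sampling site holds as many fish as were historically measured there on
average over the years matching a demographic/environmental scenario.  Each
fish then receives:

* a length (resampled from the site's observed 1-cm length frequencies,
  jittered to mm within the bin);
* a sex (observed when known, otherwise drawn from the most specific sex
  ratio supported by at least ``min_n`` known-sex fish, escalating
  cm x site -> cm x stratum -> cm -> overall);
* a true age from the quadratic size-at-age relation

      age_i = alpha + beta1(sex) * size_mm_i^2 + beta2 * rlat_i + e_i

  with a sex-specific size coefficient, a geographic coefficient on rotated
  latitude, and a site-level spatially autocorrelated Gaussian error e drawn
  from a covariogram model.  Continuous ages are discretized to integer age
  groups (round half up, clipped to [0, age_cap]).

Six scenarios select the survey years entering the resampling: warm / cold
(mean middle-shelf bottom temperature), high / low age-structure diversity
(Simpson index of the otolith ages, with stage-1/2 counts shared between the
pair), and high / low total abundance (with the pair's age compositions
constrained to differ by less than 3% at every age group).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import geometry
from .spatial import SpatialErrorModel, simulate_spatial_error

SCENARIO_LABELS = (
    "warm",
    "cold",
    "high_diversity",
    "low_diversity",
    "high_abundance",
    "low_abundance",
)

_CRITERIA = {
    "warm": ("temperature", "top"),
    "cold": ("temperature", "bottom"),
    "high_diversity": ("diversity", "top"),
    "low_diversity": ("diversity", "bottom"),
    "high_abundance": ("abundance", "top"),
    "low_abundance": ("abundance", "bottom"),
}


@dataclass(frozen=True)
class AgeModelCoefficients:
    """Coefficients of the quadratic size-at-age relation.

    ``beta1`` is per squared millimetre of length and differs by sex;
    ``beta2`` is per degree of rotated latitude.  ``alpha`` places modal
    lengths of 20-40 cm at ages 1-3.
    """

    alpha: float = 0.5
    beta1_male: float = 1.05e-5
    beta1_female: float = 1.0e-5
    beta2: float = -0.031
    size_unit: str = "mm"
    age_cap: int = 12

    def __post_init__(self):
        if self.beta1_male <= 0 or self.beta1_female <= 0:
            raise ValueError("beta1 coefficients must be positive")
        if self.size_unit not in ("mm", "cm"):
            raise ValueError("size_unit must be 'mm' or 'cm'")


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the six demographic/environmental scenarios."""

    label: str
    n_years: int = 5
    #: max absolute difference in age-composition proportions for the
    #: abundance pair
    max_age_composition_diff: float = 0.03
    max_redraws: int = 200

    def __post_init__(self):
        if self.label not in SCENARIO_LABELS:
            raise ValueError(f"label must be one of {SCENARIO_LABELS}")

    @property
    def criterion(self) -> str:
        return _CRITERIA[self.label][0]

    @property
    def direction(self) -> str:
        return _CRITERIA[self.label][1]


@dataclass
class VirtualPopulation:
    """A fully specified fish population on the survey grid."""

    scenario: ScenarioSpec
    years: tuple[int, ...]
    sites: pd.DataFrame
    fish: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def stage2_counts(self) -> pd.DataFrame:
        """Measured-fish counts per (site, 1-cm bin) — the stage-2 table."""
        out = self.fish.groupby(["site_id", "cm_bin"], as_index=False).size()
        return out.rename(columns={"size": "count"})

    def age_frequency(self) -> pd.Series:
        """True age-group counts over the whole population."""
        cap = int(self.fish["true_age"].max()) if len(self.fish) else 0
        return self.fish["true_age"].value_counts().reindex(range(cap + 1), fill_value=0).sort_index()


def discretize_age(age_cont: np.ndarray, age_cap: int) -> np.ndarray:
    """Round half up to the nearest integer age group, clipped to [0, cap]."""
    return np.clip(np.floor(np.asarray(age_cont, dtype=float) + 0.5), 0, age_cap).astype(int)


def assign_age(length_mm, sex, rotated_latitude, e_site, coeffs: AgeModelCoefficients):
    """Apply the quadratic size-at-age relation.

    Parameters are vectorized; ``length_mm`` is in millimetres regardless of
    ``coeffs.size_unit`` (lengths are converted internally when the
    coefficients are declared per cm^2).

    Returns ``(true_age_cont, true_age)``.
    """
    length_mm = np.asarray(length_mm, dtype=float)
    if np.any(length_mm <= 0):
        raise ValueError("length must be positive")
    size = length_mm if coeffs.size_unit == "mm" else length_mm / 10.0
    sex = np.asarray(sex, dtype=object)
    beta1 = np.where(sex == "male", coeffs.beta1_male, coeffs.beta1_female)
    cont = coeffs.alpha + beta1 * size**2 + coeffs.beta2 * np.asarray(rotated_latitude, dtype=float)
    cont = cont + np.asarray(e_site, dtype=float)
    return cont, discretize_age(cont, coeffs.age_cap)


def simpson_diversity(age_counts) -> float:
    """Simpson diversity 1 - sum(p_a^2) of an age composition."""
    counts = np.asarray(age_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("age counts are all zero")
    p = counts / total
    return float(1.0 - np.sum(p**2))


def select_scenario_years(
    hauls: pd.DataFrame,
    spec: ScenarioSpec,
    otoliths: pd.DataFrame | None = None,
) -> tuple[int, ...]:
    """Pick the ``n_years`` survey years that best meet the scenario criterion.

    * temperature: mean bottom temperature over middle-stratum hauls;
    * abundance: total catch count;
    * diversity: Simpson index of that year's otolith age composition
      (requires ``otoliths``).
    """
    years = np.sort(hauls["year"].unique())
    if len(years) < spec.n_years:
        raise ValueError(f"need at least {spec.n_years} distinct years, found {len(years)}")
    if spec.criterion == "temperature":
        h = hauls[geometry.depth_stratum(hauls["depth"].to_numpy()) == "middle"]
        if h.empty:
            # no middle-stratum stations: fall back to the whole-shelf mean
            h = hauls
        score = h.groupby("year")["bottom_temperature"].mean()
    elif spec.criterion == "abundance":
        score = hauls.groupby("year")["catch_count"].sum()
    else:
        if otoliths is None:
            raise ValueError("diversity scenarios need the otolith table")
        oto = otoliths.merge(hauls[["haul_id", "year"]], on="haul_id")
        score = oto.groupby("year")["age"].apply(lambda a: simpson_diversity(np.bincount(a)))
    score = score.reindex(years).dropna()
    if len(score) < spec.n_years:
        raise ValueError(
            f"criterion {spec.criterion!r} is scoreable for only {len(score)} years"
        )
    ordered = score.sort_values(ascending=(spec.direction == "bottom"), kind="stable")
    return tuple(int(y) for y in sorted(ordered.index[: spec.n_years]))


def _sex_ratio_table(source: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    grp = source.groupby(keys)["sex"]
    out = grp.agg(n="size", p_female=lambda s: float((s == "female").mean()))
    return out.reset_index()


def assign_sex(
    fish: pd.DataFrame,
    source: pd.DataFrame,
    rng: np.random.Generator,
    min_n: int = 10,
) -> np.ndarray:
    """Resolve undetermined sexes by escalating sex-ratio aggregation.

    ``fish`` and ``source`` both need columns ``site_id, stratum,
    length_bin, sex``; ratios are computed from the known-sex rows of
    ``source``.  For each undetermined fish the most specific of
    (cm x site), (cm x stratum), (cm), overall with at least ``min_n``
    known-sex fish supplies P(female).
    """
    known = source[source["sex"].isin(("male", "female"))]
    if known.empty:
        raise ValueError("no known-sex fish available to compute sex ratios")
    levels = [
        _sex_ratio_table(known, ["length_bin", "site_id"]),
        _sex_ratio_table(known, ["length_bin", "stratum"]),
        _sex_ratio_table(known, ["length_bin"]),
    ]
    overall_p = float((known["sex"] == "female").mean())

    sex = fish["sex"].to_numpy(dtype=object).copy()
    undet = np.flatnonzero(sex == "undetermined")
    if len(undet) == 0:
        return sex
    sub = fish.iloc[undet][["length_bin", "site_id", "stratum"]].reset_index(drop=True)
    p = np.full(len(sub), np.nan)
    for table, keys in zip(levels, (["length_bin", "site_id"], ["length_bin", "stratum"], ["length_bin"])):
        merged = sub.merge(table, on=keys, how="left")
        ok = np.isnan(p) & (merged["n"].to_numpy() >= min_n)
        p[ok] = merged["p_female"].to_numpy()[ok]
    p[np.isnan(p)] = overall_p
    draw = rng.random(len(p)) < p
    sex[undet] = np.where(draw, "female", "male")
    return sex


def default_spatial_model(sites: pd.DataFrame, nugget=0.05, sill=0.25, family="exponential") -> SpatialErrorModel:
    """Covariogram with range = 15% of the site-cloud diagonal."""
    lon, lat = sites["longitude"], sites["latitude"]
    diag = float(np.hypot(lon.max() - lon.min(), lat.max() - lat.min()))
    # single-site (or collinear) clouds have no meaningful diagonal
    return SpatialErrorModel(family=family, nugget=nugget, sill=sill, range_=max(0.15 * diag, 1e-6))


def _site_targets(
    lengths: pd.DataFrame,
    haul_meta: pd.DataFrame,
    years: tuple[int, ...],
    all_site_ids: pd.Series,
) -> pd.Series:
    """Per-site target fish count: mean measured count over the years, rounded."""
    counted = lengths.merge(haul_meta[["haul_id", "year", "site_id"]], on="haul_id")
    counted = counted[counted["year"].isin(years)]
    per_sy = counted.groupby(["site_id", "year"])["count"].sum().unstack(fill_value=0)
    per_sy = per_sy.reindex(columns=list(years), fill_value=0)
    target = np.floor(per_sy.mean(axis=1) + 0.5).astype(int)
    return target.reindex(all_site_ids, fill_value=0)


def _resample_fish(
    pool: pd.DataFrame,
    targets: pd.Series,
    sites: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw per-site lengths (with replacement) from the scenario-year pool."""
    site_meta = sites.set_index("site_id")
    pools = {sid: grp for sid, grp in pool.groupby("site_id")}
    stratum_pools = {s: grp for s, grp in pool.merge(
        sites[["site_id", "stratum"]], on="site_id").groupby("stratum")}
    rows = []
    for sid, n in targets.items():
        if n <= 0:
            continue
        src = pools.get(sid)
        if src is None or src.empty:
            # site never measured in the scenario years: borrow its stratum pool
            src = stratum_pools.get(site_meta.loc[sid, "stratum"], pool)
        idx = rng.integers(0, len(src), size=n)
        drawn = src.iloc[idx][["length_bin", "sex"]].reset_index(drop=True)
        drawn.insert(0, "site_id", sid)
        rows.append(drawn)
    if not rows:
        raise ValueError("no fish to resample: all site targets are zero")
    return pd.concat(rows, ignore_index=True)


def build_population(
    hauls: pd.DataFrame,
    lengths: pd.DataFrame,
    spec: ScenarioSpec,
    coeffs: AgeModelCoefficients | None = None,
    spatial_model: SpatialErrorModel | None = None,
    seed: int | np.random.Generator = 0,
    otoliths: pd.DataFrame | None = None,
    sites: pd.DataFrame | None = None,
    years: tuple[int, ...] | None = None,
    min_n_sex_ratio: int = 10,
    fish_noise_sd: float = 0.0,
    rotation_angle: float = geometry.DEFAULT_ROTATION_ANGLE,
) -> VirtualPopulation:
    """Build the virtual population for one scenario.

    ``years`` overrides scenario-year selection (used by the diversity pair,
    which shares stage-1/2 counts, and by the abundance-pair constraint
    loop).  ``fish_noise_sd`` adds optional per-fish independent age noise on
    top of the site-level field (default off).
    """
    coeffs = coeffs or AgeModelCoefficients()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sites is None:
        sites = geometry.build_site_table(hauls, rotation_angle=rotation_angle)
    if spatial_model is None:
        spatial_model = default_spatial_model(sites)
    haul_meta = hauls.merge(sites[["site_id", "longitude", "latitude"]], on=["longitude", "latitude"])
    if years is None:
        years = select_scenario_years(hauls, spec, otoliths)
    if spec.criterion == "diversity":
        # the diversity pair shares stage-1/stage-2 counts: compute targets
        # over ALL years so high_ and low_diversity populations coincide
        target_years = tuple(int(y) for y in np.sort(hauls["year"].unique()))
    else:
        target_years = years
    targets = _site_targets(lengths, haul_meta, target_years, sites["site_id"])

    tagged = lengths.merge(haul_meta[["haul_id", "year", "site_id"]], on="haul_id")
    tagged = tagged[tagged["year"].isin(years)]
    reps = np.repeat(tagged.index.to_numpy(), tagged["count"].to_numpy())
    pool = tagged.loc[reps, ["site_id", "length_bin", "sex"]].reset_index(drop=True)

    fish = _resample_fish(pool, targets, sites, rng)
    fish = fish.merge(
        sites[
            [
                "site_id",
                "longitude",
                "latitude",
                "rotated_latitude",
                "stratum",
                "area",
                "route_index",
            ]
        ],
        on="site_id",
        how="left",
    )
    source = pool.merge(sites[["site_id", "stratum"]], on="site_id", how="left")
    fish["sex"] = assign_sex(fish, source, rng, min_n=min_n_sex_ratio)
    fish["length_mm"] = fish["length_bin"] * 10.0 + rng.uniform(0.0, 10.0, size=len(fish))
    fish["cm_bin"] = fish["length_bin"].astype(int)

    e_site = simulate_spatial_error(
        sites[["longitude", "latitude"]].to_numpy(), spatial_model, rng
    )
    e_by_site = pd.Series(e_site, index=sites["site_id"])
    e = e_by_site.reindex(fish["site_id"]).to_numpy()
    if fish_noise_sd > 0:
        e = e + rng.normal(0.0, fish_noise_sd, size=len(fish))
    cont, group = assign_age(
        fish["length_mm"].to_numpy(),
        fish["sex"].to_numpy(),
        fish["rotated_latitude"].to_numpy(),
        e,
        coeffs,
    )
    fish["true_age_cont"] = cont
    fish["true_age"] = group
    fish.insert(0, "fish_id", np.arange(len(fish)))
    fish = fish.drop(columns=["length_bin"])
    return VirtualPopulation(
        scenario=spec,
        years=tuple(years),
        sites=sites,
        fish=fish,
        provenance={
            "coeffs": asdict(coeffs),
            "spatial_model": asdict(spatial_model),
            "fish_noise_sd": fish_noise_sd,
        },
    )


def age_composition(pop: VirtualPopulation, age_cap: int = 12) -> np.ndarray:
    counts = np.bincount(pop.fish["true_age"].to_numpy(), minlength=age_cap + 1)
    return counts / counts.sum()


def build_abundance_pair(
    hauls,
    lengths,
    coeffs=None,
    spatial_model=None,
    seed: int = 0,
    otoliths=None,
    **kwargs,
):
    """Build the high/low abundance pair under the age-composition constraint.

    The high-abundance population is built once; the low-abundance build is
    re-drawn (new resampling randomness, same years) until every age group's
    composition proportion is within ``max_age_composition_diff`` of the
    high-abundance one, or ``max_redraws`` is exhausted.
    """
    rng = np.random.default_rng(seed)
    spec_hi = ScenarioSpec("high_abundance")
    spec_lo = ScenarioSpec("low_abundance")
    hi = build_population(
        hauls, lengths, spec_hi, coeffs, spatial_model, rng, otoliths=otoliths, **kwargs
    )
    worst = np.inf
    for _ in range(spec_lo.max_redraws):
        lo = build_population(
            hauls, lengths, spec_lo, coeffs, spatial_model, rng, otoliths=otoliths, **kwargs
        )
        diff = np.abs(age_composition(hi) - age_composition(lo)).max()
        worst = min(worst, diff)
        if diff <= spec_lo.max_age_composition_diff:
            return hi, lo
    raise RuntimeError(
        "abundance pair constraint unsatisfied after "
        f"{spec_lo.max_redraws} redraws (best max per-age discrepancy {worst:.4f})"
    )


def build_diversity_pair(hauls, lengths, otoliths, coeffs=None, spatial_model=None, seed: int = 0, **kwargs):
    """Build the high/low diversity pair (shared stage-1/stage-2 counts)."""
    rng = np.random.default_rng(seed)
    hi = build_population(
        hauls, lengths, ScenarioSpec("high_diversity"), coeffs, spatial_model, rng, otoliths=otoliths, **kwargs
    )
    lo = build_population(
        hauls, lengths, ScenarioSpec("low_diversity"), coeffs, spatial_model, rng, otoliths=otoliths, **kwargs
    )
    return hi, lo
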