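"""Synthetic multi-stage survey generator.

Emulates the statistical structure of an eastern Bering Sea style bottom-trawl
survey so the whole evaluation pipeline runs with no external data:

* a fixed square grid of sampling sites (default 375) revisited every year,
  with a cruise route that starts at the SE end of the shelf and works NW;
* inner / middle / outer depth strata across the shelf and a NW/SE area split;
* a smooth cross-shelf bottom-temperature surface with inter-annual
  variability and a warm/cold regime shift (cold regimes put much of the
  middle shelf below the 2 °C cold-pool threshold);
* stage-2 length frequencies drawn from a multimodal mixture whose modes
  correspond to young age groups, with mode weights tilted along the shelf so
  mean size (hence age) has a monotone spatial gradient;
* a historical stage-3 otolith table collected length-stratified (3 fish per
  1-cm bin x sex x area per year), aged with the same quadratic size-at-age
  relation the virtual population uses plus noise.

Everything is a pure function of the config and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry
from .io import validate_hauls, validate_lengths, validate_otoliths

#: default length-mixture modes (cm): the lengths at which the default
#: quadratic size-at-age relation crosses integer ages 1..6
DEFAULT_MODE_MEANS = (22.0, 39.0, 50.0, 59.0, 67.0, 74.0)
DEFAULT_MODE_SDS = (3.0, 4.0, 4.5, 5.0, 5.0, 6.0)
DEFAULT_MODE_WEIGHTS = (0.18, 0.30, 0.22, 0.14, 0.09, 0.07)

#: regime shifts (°C) applied to the mean temperature surface
REGIME_OFFSETS = {"warm": 0.5, "cold": -2.5}


@dataclass
class SyntheticSurveyConfig:
    """Parameters of the synthetic survey.

    Defaults are the study conditions: 375 grid sites, ten survey years,
    roughly 30 measured fish per site and year, age-mode lengths consistent
    with the default size-at-age coefficients, and a cross-shelf age
    gradient.
    """

    n_sites: int = 375
    lon_range: tuple[float, float] = (-175.0, -160.0)
    lat_range: tuple[float, float] = (54.5, 62.0)
    n_years: int = 10
    first_year: int = 2007
    regime: str = "warm"
    #: inter-annual s.d. of the year temperature effect (°C)
    temp_year_sd: float = 0.8
    #: site-level temperature noise (°C)
    temp_site_sd: float = 0.4
    #: mean measured fish per site and year
    mean_catch: float = 30.0
    #: log-scale s.d. of the year abundance effect
    abundance_year_sd: float = 0.35
    #: log-scale cross-shelf abundance tilt (inner > outer for positive values)
    abundance_gradient: float = 0.8
    mode_means: tuple[float, ...] = DEFAULT_MODE_MEANS
    mode_sds: tuple[float, ...] = DEFAULT_MODE_SDS
    mode_weights: tuple[float, ...] = DEFAULT_MODE_WEIGHTS
    #: log-odds tilt of age-mode weights along rotated latitude (spatial
    #: size/age structure; 0 disables the gradient)
    age_gradient: float = 0.9
    #: logistic sex-ratio curve: P(female | length)
    sex_ratio_midpoint: float = 50.0
    sex_ratio_scale: float = 40.0
    #: probability a measured fish's sex is undetermined, small vs large fish
    undetermined_small: float = 0.35
    undetermined_large: float = 0.05
    undetermined_length_cut: float = 20.0
    #: historical otolith collection quota per (cm bin, sex, area, year)
    otolith_quota: int = 3
    #: s.d. (years) of the noise on historical otolith ages
    otolith_age_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.lon_range[0] >= self.lon_range[1] or self.lat_range[0] >= self.lat_range[1]:
            raise ValueError("degenerate grid extent")
        if self.regime not in REGIME_OFFSETS:
            raise ValueError(f"regime must be one of {sorted(REGIME_OFFSETS)}")
        w = np.asarray(self.mode_weights, dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("mode_weights must sum to 1")
        if not (len(self.mode_means) == len(self.mode_sds) == len(self.mode_weights)):
            raise ValueError("mode_means, mode_sds, mode_weights must have equal length")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSurveyConfig":
        d = dict(d)
        for key in ("lon_range", "lat_range", "mode_means", "mode_sds", "mode_weights"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSurveyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _site_grid(config: SyntheticSurveyConfig) -> pd.DataFrame:
    """Lay n_sites on a near-square grid over the lon/lat rectangle."""
    n = config.n_sites
    ncols = int(np.ceil(np.sqrt(n * 1.6)))  # wider than tall, like a shelf
    nrows = int(np.ceil(n / ncols))
    lon = np.linspace(*config.lon_range, ncols)
    lat = np.linspace(*config.lat_range, nrows)
    gx, gy = np.meshgrid(lon, lat)
    sites = pd.DataFrame({"longitude": gx.ravel()[:n], "latitude": gy.ravel()[:n]})
    # normalized coordinates within the rectangle
    xn = (sites["longitude"] - config.lon_range[0]) / (config.lon_range[1] - config.lon_range[0])
    yn = (sites["latitude"] - config.lat_range[0]) / (config.lat_range[1] - config.lat_range[0])
    # cross-shelf coordinate: 0 at the shallow (SE/inner) corner, 1 at the
    # deep (NW/outer) corner, constant along the NW–SE shelf axis
    v = np.clip((xn.to_numpy() * 0.0 + (1.0 - xn.to_numpy()) + yn.to_numpy()) / 2.0, 0.0, 1.0)
    sites["cross_shelf"] = v
    sites["depth"] = np.clip(15.0 + 185.0 * v**1.3, 5.0, 199.0)
    # along-shelf coordinate (SE -> NW), used for the age gradient and route
    g = (xn.to_numpy() + yn.to_numpy()) / 2.0
    sites["along_shelf"] = g
    return sites


def generate_synthetic_survey(config: SyntheticSurveyConfig):
    """Generate (hauls, lengths, otoliths) tables for the configured survey.

    Returns three validated DataFrames in the formats of :mod:`surveysub.io`.
    Identical config (including seed) gives identical tables.
    """
    rng = np.random.default_rng(config.seed)
    sites = _site_grid(config)
    n_sites = len(sites)
    v = sites["cross_shelf"].to_numpy()
    g = sites["along_shelf"].to_numpy()
    g_norm = (g - g.min()) / max(g.max() - g.min(), 1e-12)

    modes = np.asarray(config.mode_means)
    sds = np.asarray(config.mode_sds)
    base_w = np.asarray(config.mode_weights)
    n_modes = len(modes)
    mode_idx_centered = np.arange(n_modes) - (n_modes - 1) / 2.0
    # per-site age-mode weights, tilted along the shelf
    tilt = np.exp(config.age_gradient * np.outer(g_norm - 0.5, mode_idx_centered))
    site_w = base_w * tilt
    site_w /= site_w.sum(axis=1, keepdims=True)
    site_cumw = np.cumsum(site_w, axis=1)

    regime_offset = REGIME_OFFSETS[config.regime]
    years = np.arange(config.first_year, config.first_year + config.n_years)
    year_temp = rng.normal(0.0, config.temp_year_sd, size=config.n_years)
    year_abund = rng.normal(0.0, config.abundance_year_sd, size=config.n_years)

    haul_rows = []
    length_frames = []
    otolith_frames = []
    for yi, year in enumerate(years):
        temp = (
            4.5
            - 3.5 * v
            + regime_offset
            + year_temp[yi]
            + rng.normal(0.0, config.temp_site_sd, size=n_sites)
        )
        lam = config.mean_catch * np.exp(config.abundance_gradient * (0.5 - v) + year_abund[yi])
        catch = rng.poisson(lam)
        catch = np.maximum(catch, 1)  # a station with zero catch is re-fished

        # one fish per row, vectorized over the whole year
        fish_site = np.repeat(np.arange(n_sites), catch)
        u = rng.random(len(fish_site))
        mode = (u[:, None] > site_cumw[fish_site]).sum(axis=1)
        length = rng.normal(modes[mode], sds[mode])
        length = np.clip(length, 6.0, 119.0)
        p_female = 1.0 / (1.0 + np.exp(-(length - config.sex_ratio_midpoint) / config.sex_ratio_scale))
        sex = np.where(rng.random(len(length)) < p_female, "female", "male").astype(object)
        p_undet = np.where(
            length < config.undetermined_length_cut, config.undetermined_small, config.undetermined_large
        )
        undet = rng.random(len(length)) < p_undet
        sex_rec = sex.copy()
        sex_rec[undet] = "undetermined"
        cm_bin = np.floor(length).astype(int)

        haul_ids = np.array([f"Y{year}-S{s:04d}" for s in range(n_sites)])
        weight = np.bincount(fish_site, weights=8.7e-6 * length**3, minlength=n_sites)
        haul_rows.append(
            pd.DataFrame(
                {
                    "haul_id": haul_ids,
                    "date": f"{year}-06-15",
                    "year": year,
                    "longitude": sites["longitude"],
                    "latitude": sites["latitude"],
                    "depth": sites["depth"].round(1),
                    "bottom_temperature": np.round(temp, 2),
                    "catch_count": catch,
                    "catch_weight": np.round(weight, 2),
                }
            )
        )
        lf = (
            pd.DataFrame(
                {"haul_id": haul_ids[fish_site], "length_bin": cm_bin, "sex": sex_rec, "count": 1}
            )
            .groupby(["haul_id", "length_bin", "sex"], as_index=False)["count"]
            .sum()
        )
        length_frames.append(lf)
        otolith_frames.append(
            _collect_historical_otoliths(
                config, rng, year, sites, fish_site, length, sex, undet, haul_ids
            )
        )

    hauls = pd.concat(haul_rows, ignore_index=True)
    lengths = pd.concat(length_frames, ignore_index=True)
    otoliths = pd.concat(otolith_frames, ignore_index=True)
    hauls = validate_hauls(hauls)
    lengths = validate_lengths(lengths, hauls)
    otoliths = validate_otoliths(otoliths, hauls)
    return hauls, lengths, otoliths


def _collect_historical_otoliths(config, rng, year, sites, fish_site, length, sex, undet, haul_ids):
    """Length-stratified historical otolith collection for one survey year.

    Walks sites in cruise order taking up to ``otolith_quota`` known-sex fish
    per (1-cm bin, sex, area) cell, then ages them with the default quadratic
    size-at-age relation plus noise (the ages only drive scenario selection
    by age-structure diversity, so an approximate relation suffices).
    """
    from .population import AgeModelCoefficients, assign_age  # local: avoid cycle at import time

    g = sites["along_shelf"].to_numpy()
    route_order = np.argsort(g, kind="stable")
    area = np.where(g > np.median(g), "NW", "SE")
    rlat_proxy = (g - g.mean()) * (config.lat_range[1] - config.lat_range[0])

    keep_rows = []
    quota: dict[tuple, int] = {}
    known = ~undet
    cm_bin = np.floor(length).astype(int)
    for s in route_order:
        at_site = np.flatnonzero((fish_site == s) & known)
        if len(at_site) == 0:
            continue
        at_site = rng.permutation(at_site)
        for i in at_site:
            key = (cm_bin[i], sex[i], area[s])
            got = quota.get(key, 0)
            if got < config.otolith_quota:
                quota[key] = got + 1
                keep_rows.append(i)
    keep = np.array(sorted(keep_rows), dtype=int)
    if len(keep) == 0:
        return pd.DataFrame(columns=["haul_id", "length", "sex", "age"])
    coeffs = AgeModelCoefficients()
    noise = rng.normal(0.0, config.otolith_age_sd, size=len(keep))
    _, age = assign_age(
        length_mm=length[keep] * 10.0,
        sex=np.asarray(sex, dtype=object)[keep],
        rotated_latitude=rlat_proxy[fish_site[keep]],
        e_site=noise,
        coeffs=coeffs,
    )
    return pd.DataFrame(
        {
            "haul_id": haul_ids[fish_site[keep]],
            "length": np.round(length[keep], 1),
            "sex": np.asarray(sex, dtype=object)[keep],
            "age": age,
        }
    )
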