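import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from surveysub.designs import (
    DesignConfig,
    census_subsample,
    match_sample_size,
    random_subsample,
    select_age_sites,
    stratified_subsample,
)
from surveysub.population import ScenarioSpec, VirtualPopulation


def _toy_population(fish_rows, site_rows):
    sites = pd.DataFrame(site_rows)
    fish = pd.DataFrame(fish_rows)
    fish.insert(0, "fish_id", np.arange(len(fish)))
    return VirtualPopulation(ScenarioSpec("warm"), (2000,), sites, fish)


def _two_site_population():
    """10 identical 50-cm females at site A (route 0), 5 at site B (route 1)."""
    sites = [
        {"site_id": "A", "longitude": -170.0, "latitude": 56.0, "rotated_latitude": -1.0,
         "depth": 40.0, "stratum": "inner", "area": "SE", "route_index": 0},
        {"site_id": "B", "longitude": -169.0, "latitude": 57.0, "rotated_latitude": 1.0,
         "depth": 40.0, "stratum": "inner", "area": "SE", "route_index": 1},
    ]
    fish = [
        {"site_id": sid, "longitude": -170.0, "latitude": 56.0, "rotated_latitude": 0.0,
         "stratum": "inner", "area": "SE", "route_index": ri, "length_mm": 505.0,
         "sex": "female", "cm_bin": 50, "true_age_cont": 3.0, "true_age": 3}
        for sid, ri, n in (("A", 0, 10), ("B", 1, 5))
        for _ in range(n)
    ]
    return _toy_population(fish, sites)


class TestPreselection:
    def test_floor_of_fraction(self, warm_population, rng):
        n = len(warm_population.sites)
        chosen = select_age_sites(warm_population.sites, 0.5, rng)
        assert len(chosen) == n // 2
        assert len(set(chosen)) == len(chosen)

    def test_fraction_one_takes_all(self, warm_population, rng):
        assert len(select_age_sites(warm_population.sites, 1.0, rng)) == len(warm_population.sites)

    def test_shared_preselection_across_designs(self, warm_population):
        rng = np.random.default_rng(0)
        pre = select_age_sites(warm_population.sites, 0.5, rng)
        rs = random_subsample(warm_population, pre, DesignConfig(kind="random"), np.random.default_rng(1))
        lss = stratified_subsample(
            warm_population, pre, DesignConfig(kind="length_stratified"), np.random.default_rng(2)
        )
        assert rs.sites_visited == lss.sites_visited == pre


class TestRandomDesign:
    def test_exactly_min_of_quota_and_catch(self, warm_population, rng):
        pre = select_age_sites(warm_population.sites, 0.5, rng)
        rs = random_subsample(warm_population, pre, DesignConfig(kind="random"), rng)
        per_site = rs.records.groupby("site_id").size()
        catch = warm_population.fish.groupby("site_id").size()
        for sid in pre:
            expected = min(4, catch.get(sid, 0))
            assert per_site.get(sid, 0) == expected
        assert rs.records["fish_id"].is_unique

    def test_inclusion_frequencies_uniform(self):
        pop = _two_site_population()
        hits = np.zeros(10)
        for rep in range(1000):
            rs = random_subsample(pop, ("A",), DesignConfig(kind="random"), np.random.default_rng(rep))
            hits[rs.records["fish_id"].to_numpy()] += 1
        p = 4 / 10
        # simultaneous bound over 10 cells (z ~ 99.9% per cell)
        bound = 3.3 * np.sqrt(p * (1 - p) / 1000)
        assert np.all(np.abs(hits / 1000 - p) < bound)


class TestStratifiedDesign:
    def test_two_site_quota_ledger_hand_example(self, rng):
        """Quota 3 per (cm, sex, area): all fish identical, so 3 come from the
        route-first site and none from the second, which is recorded skipped."""
        pop = _two_site_population()
        lss = stratified_subsample(pop, ("A", "B"), DesignConfig(kind="length_stratified"), rng)
        assert len(lss.records) == 3
        assert (lss.records["site_id"] == "A").all()
        assert lss.sites_skipped == ("B",)

    def test_cell_quota_never_exceeded(self, warm_population, rng):
        pre = select_age_sites(warm_population.sites, 0.5, rng)
        lss = stratified_subsample(warm_population, pre, DesignConfig(kind="length_stratified"), rng)
        cells = lss.records.groupby(["cm_bin", "sex", "area"]).size()
        assert (cells <= 3).all()
        n_bins = lss.records["cm_bin"].nunique()
        assert len(lss.records) <= 3 * n_bins * 2 * 2
        assert lss.records["fish_id"].is_unique

    def test_only_eligible_site_collects(self, rng):
        pop = _two_site_population()
        lss = stratified_subsample(pop, ("B",), DesignConfig(kind="length_stratified"), rng)
        assert (lss.records["site_id"] == "B").all()
        assert len(lss.records) == 3

    def test_route_order_biases_collection_toward_early_sites(self, warm_population):
        """When length cells are shared across sites, quota exhaustion makes
        LSS take progressively fewer fish along the route."""
        rhos = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pre = select_age_sites(warm_population.sites, 1.0, rng)
            lss = stratified_subsample(
                warm_population, pre, DesignConfig(kind="length_stratified"), rng
            )
            per_site = lss.records.groupby("site_id").size()
            route = warm_population.sites.set_index("site_id")["route_index"]
            counts = per_site.reindex(route.index, fill_value=0)
            rhos.append(spearmanr(route.to_numpy(), counts.to_numpy()).statistic)
        assert np.mean(rhos) < -0.2


class TestCensusAndMatching:
    def test_census_takes_everything_and_nests_random(self, warm_population, rng):
        pre = select_age_sites(warm_population.sites, 0.5, rng)
        cen = census_subsample(warm_population, pre)
        expected = warm_population.fish["site_id"].isin(pre).sum()
        assert len(cen.records) == expected
        rs = random_subsample(warm_population, pre, DesignConfig(kind="random"), rng)
        assert set(rs.records["fish_id"]) <= set(cen.records["fish_id"])

    def test_census_age_frequency_matches_population_restriction(self, warm_population, rng):
        pre = select_age_sites(warm_population.sites, 0.5, rng)
        cen = census_subsample(warm_population, pre)
        truth = warm_population.fish[warm_population.fish["site_id"].isin(pre)]
        pd.testing.assert_series_equal(
            cen.records["true_age"].value_counts().sort_index(),
            truth["true_age"].value_counts().sort_index(),
        )

    def test_match_sample_size(self, warm_population, rng):
        pre = select_age_sites(warm_population.sites, 0.5, rng)
        rs = random_subsample(warm_population, pre, DesignConfig(kind="random"), rng)
        matched = match_sample_size(rs, len(rs.records) - 20, rng)
        assert len(matched.records) == len(rs.records) - 20
        assert matched.design.kind == "random_matched"
        assert set(matched.records["fish_id"]) <= set(rs.records["fish_id"])
        same = match_sample_size(rs, len(rs.records), rng)
        assert len(same.records) == len(rs.records)
        with pytest.raises(ValueError):
            match_sample_size(rs, len(rs.records) + 1, rng)

    def test_matched_inclusion_is_uniform(self):
        pop = _two_site_population()
        base = random_subsample(pop, ("A", "B"), DesignConfig(kind="random"), np.random.default_rng(0))
        n = len(base.records)  # 8 records
        base_ids = base.records["fish_id"].tolist()
        hits = np.zeros(n)
        for rep in range(1000):
            m = match_sample_size(base, 4, np.random.default_rng(rep))
            for fid in m.records["fish_id"]:
                hits[base_ids.index(fid)] += 1
        p = 4 / n
        # simultaneous bound over the 8 records
        bound = 3.3 * np.sqrt(p * (1 - p) / 1000)
        assert np.all(np.abs(hits / 1000 - p) < bound)
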