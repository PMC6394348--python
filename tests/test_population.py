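import numpy as np
import pandas as pd
import pytest

from surveysub.population import (
    AgeModelCoefficients,
    ScenarioSpec,
    age_composition,
    assign_age,
    assign_sex,
    build_abundance_pair,
    build_diversity_pair,
    build_population,
    discretize_age,
    select_scenario_years,
    simpson_diversity,
)
from surveysub.spatial import SpatialErrorModel, morans_i


class TestAgeRelation:
    def test_printed_coefficients_reproduce_hand_computed_ages(self):
        coeffs = AgeModelCoefficients(alpha=0.0)
        cont_f, _ = assign_age([800.0], ["female"], [0.0], [0.0], coeffs)
        cont_m, _ = assign_age([800.0], ["male"], [0.0], [0.0], coeffs)
        assert cont_f[0] == pytest.approx(6.4, abs=0)
        assert cont_m[0] == pytest.approx(6.72, abs=0)

    def test_rotated_latitude_contrast_is_geographic_coefficient(self):
        coeffs = AgeModelCoefficients()
        a0, _ = assign_age([500.0], ["female"], [0.0], [0.0], coeffs)
        a1, _ = assign_age([500.0], ["female"], [1.0], [0.0], coeffs)
        assert a1[0] - a0[0] == pytest.approx(-0.031, abs=1e-15)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            assign_age([0.0], ["male"], [0.0], [0.0], AgeModelCoefficients())

    def test_discretization_rounds_half_up_and_clips(self):
        ages = discretize_age(np.array([-0.7, 0.49, 0.5, 2.5, 13.2]), age_cap=12)
        assert ages.tolist() == [0, 0, 1, 3, 12]

    def test_cm_coefficients_supported(self):
        coeffs = AgeModelCoefficients(alpha=0.0, beta1_female=1e-3, size_unit="cm")
        cont, _ = assign_age([800.0], ["female"], [0.0], [0.0], coeffs)  # 80 cm
        assert cont[0] == pytest.approx(6.4)


class TestSimpson:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([10], 0.0),
            ([5, 5, 5, 5], 0.75),
            ([2, 1, 1], 0.625),
        ],
    )
    def test_closed_form_values(self, counts, expected):
        assert simpson_diversity(counts) == pytest.approx(expected)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            simpson_diversity([0, 0])


class TestScenarioYears:
    def _hauls_with_trends(self):
        rows = []
        for i, year in enumerate(range(2000, 2010)):
            for s in range(4):
                rows.append(
                    {
                        "haul_id": f"{year}-{s}",
                        "date": f"{year}-06-01",
                        "year": year,
                        "longitude": -170.0 + s,
                        "latitude": 56.0 + s,
                        "depth": 75.0,  # all middle stratum
                        "bottom_temperature": i * 0.5,  # monotone warming
                        "catch_count": 100 + 10 * i,  # monotone increase
                        "catch_weight": 1.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_top5_by_injected_abundance_and_temperature(self):
        hauls = self._hauls_with_trends()
        high = select_scenario_years(hauls, ScenarioSpec("high_abundance"))
        assert high == tuple(range(2005, 2010))
        warm = select_scenario_years(hauls, ScenarioSpec("warm"))
        assert warm == tuple(range(2005, 2010))
        cold = select_scenario_years(hauls, ScenarioSpec("cold"))
        assert cold == tuple(range(2000, 2005))

    def test_high_low_selections_disjoint_given_ten_years(self):
        hauls = self._hauls_with_trends()
        hi = set(select_scenario_years(hauls, ScenarioSpec("high_abundance")))
        lo = set(select_scenario_years(hauls, ScenarioSpec("low_abundance")))
        assert hi.isdisjoint(lo)

    def test_fewer_than_five_years_error(self):
        hauls = self._hauls_with_trends().query("year < 2003")
        with pytest.raises(ValueError, match="5 distinct years"):
            select_scenario_years(hauls, ScenarioSpec("warm"))


class TestSexAssignment:
    def _frame(self, n, sex, site="A", stratum="inner", length_bin=30):
        return pd.DataFrame(
            {
                "site_id": [site] * n,
                "stratum": [stratum] * n,
                "length_bin": [length_bin] * n,
                "sex": sex if isinstance(sex, list) else [sex] * n,
            }
        )

    def test_degenerate_all_female_cell(self, rng):
        source = self._frame(20, "female")
        fish = self._frame(5, "undetermined")
        out = assign_sex(fish, source, rng)
        assert (out == "female").all()

    def test_small_cell_escalates_to_stratum_ratio(self, rng):
        # site A has 4 known fish (all male) -> below min_n, so the stratum
        # ratio (all female) must be used instead
        site_a = self._frame(4, "male", site="A")
        site_b = self._frame(30, "female", site="B")
        source = pd.concat([site_a, site_b], ignore_index=True)
        fish = self._frame(10, "undetermined", site="A")
        out = assign_sex(fish, source, rng, min_n=10)
        frac_female = (out == "female").mean()
        # stratum-level ratio is 30/34 female; site-level would be 0
        assert frac_female > 0.5

    def test_large_sample_frequencies_match_source_ratio(self, rng):
        p = 0.3
        sexes = ["female" if i < 300 else "male" for i in range(1000)]
        source = self._frame(1000, sexes)
        fish = self._frame(4000, "undetermined")
        out = assign_sex(fish, source, rng)
        phat = (out == "female").mean()
        # binomial 99% bound at n=4000
        bound = 2.58 * np.sqrt(p * (1 - p) / 4000)
        assert abs(phat - p) < bound

    def test_no_known_sex_anywhere_errors(self, rng):
        source = self._frame(5, "undetermined")
        with pytest.raises(ValueError, match="no known-sex"):
            assign_sex(self._frame(2, "undetermined"), source, rng)


def _single_site_tables(count_per_year=12):
    rows, lrows = [], []
    for year in range(2000, 2005):
        hid = f"{year}-A"
        rows.append(
            {
                "haul_id": hid,
                "date": f"{year}-06-01",
                "year": year,
                "longitude": -170.0,
                "latitude": 56.0,
                "depth": 40.0,
                "bottom_temperature": 2.0,
                "catch_count": count_per_year,
                "catch_weight": 5.0,
            }
        )
        lrows.append({"haul_id": hid, "length_bin": 30, "sex": "female", "count": count_per_year})
    return pd.DataFrame(rows), pd.DataFrame(lrows)


class TestBuildPopulation:
    def test_constant_counts_resample_exactly(self):
        hauls, lengths = _single_site_tables(12)
        pop = build_population(hauls, lengths, ScenarioSpec("warm"), seed=0)
        assert len(pop.fish) == 12
        assert (pop.fish["site_id"] == pop.sites["site_id"].iloc[0]).all()

    def test_seed_determinism(self, small_survey):
        hauls, lengths, otoliths = small_survey
        a = build_population(hauls, lengths, ScenarioSpec("cold"), seed=3, otoliths=otoliths)
        b = build_population(hauls, lengths, ScenarioSpec("cold"), seed=3, otoliths=otoliths)
        pd.testing.assert_frame_equal(a.fish, b.fish)

    def test_ages_clipped_to_valid_range(self, warm_population):
        ages = warm_population.fish["true_age"]
        assert ages.between(0, 12).all()

    def test_coefficient_recovery_from_noiseless_population(self, small_survey):
        """Regressing continuous age on length^2, sex and rotated latitude
        over a zero-error population returns the configured coefficients."""
        hauls, lengths, otoliths = small_survey
        zero = SpatialErrorModel(nugget=0.0, sill=0.0, range_=1.0)
        pop = build_population(
            hauls, lengths, ScenarioSpec("warm"), spatial_model=zero, seed=8, otoliths=otoliths
        )
        f = pop.fish
        male = (f["sex"] == "male").to_numpy().astype(float)
        X = np.column_stack(
            [
                np.ones(len(f)),
                f["length_mm"] ** 2 * male,
                f["length_mm"] ** 2 * (1 - male),
                f["rotated_latitude"],
            ]
        )
        beta, *_ = np.linalg.lstsq(X, f["true_age_cont"].to_numpy(), rcond=None)
        expected = [0.5, 1.05e-5, 1.0e-5, -0.031]
        np.testing.assert_allclose(beta, expected, atol=1e-8)

    def test_site_error_leaves_positive_spatial_autocorrelation(self, small_survey, rng):
        """Site-mean residuals of the age relation must be spatially
        autocorrelated when sill > nugget, and not when sill == nugget."""
        hauls, lengths, otoliths = small_survey
        outcomes = {}
        for name, model in {
            "structured": SpatialErrorModel(nugget=0.02, sill=0.5, range_=4.0),
            "nugget_only": SpatialErrorModel(nugget=0.5, sill=0.5, range_=4.0),
        }.items():
            pop = build_population(
                hauls, lengths, ScenarioSpec("warm"), spatial_model=model, seed=21, otoliths=otoliths
            )
            f = pop.fish
            coeffs = AgeModelCoefficients()
            beta1 = np.where(f["sex"] == "male", coeffs.beta1_male, coeffs.beta1_female)
            mean_structure = coeffs.alpha + beta1 * f["length_mm"] ** 2 + coeffs.beta2 * f["rotated_latitude"]
            resid = f["true_age_cont"] - mean_structure
            site = f.assign(resid=resid).groupby("site_id").agg(
                lon=("longitude", "first"), lat=("latitude", "first"), r=("resid", "mean")
            )
            outcomes[name] = morans_i(site[["lon", "lat"]].to_numpy(), site["r"].to_numpy(), rng)
        assert outcomes["structured"]["I"] > 0.2
        assert outcomes["structured"]["p_value"] < 0.01
        # null arm: magnitude indistinguishable from the no-autocorrelation
        # expectation (-1/(n-1) ~ 0), well below the structured arm
        assert abs(outcomes["nugget_only"]["I"]) < 0.1


class TestScenarioPairs:
    def test_diversity_pair_shares_site_counts(self, small_survey):
        hauls, lengths, otoliths = small_survey
        hi, lo = build_diversity_pair(hauls, lengths, otoliths, seed=4)
        counts_hi = hi.fish.groupby("site_id").size()
        counts_lo = lo.fish.groupby("site_id").size()
        pd.testing.assert_series_equal(counts_hi, counts_lo)

    def test_abundance_pair_age_compositions_within_3_percent(self, small_survey):
        hauls, lengths, otoliths = small_survey
        hi, lo = build_abundance_pair(hauls, lengths, seed=4, otoliths=otoliths)
        diff = np.abs(age_composition(hi) - age_composition(lo)).max()
        assert diff <= 0.03
        assert len(hi.fish) != len(lo.fish)  # the pair really differs in abundance
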