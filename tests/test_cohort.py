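"""Synthetic cohort generator, eligibility filter and descriptives."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from pasenorm import cohort as ch
from pasenorm.cohort import (DEFAULT_SPEC, GeneratorSpec, apply_exclusions,
                             assign_season, compare_included_excluded,
                             generate_cohort, true_centile,
                             weighted_descriptives)
from pasenorm.distributions import get_family


class TestGeneratorSpec:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="n"):
            GeneratorSpec(n=0)

    def test_positive_shift_rejected(self):
        with pytest.raises(ValueError, match="shift"):
            GeneratorSpec(excluded_shift=5.0)

    def test_degenerate_truth_curve_rejected(self):
        bad = ch.SexTruth(family="SHASHo2", mu_at_45=100, mu_slope=-1,
                          sigma_at_45=10, sigma_slope=-1, nu=0, tau=1)
        with pytest.raises(ValueError, match="domain"):
            GeneratorSpec(male=bad)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        spec = DEFAULT_SPEC.replace(n=500)
        a = generate_cohort(spec, seed=3)
        b = generate_cohort(spec, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_no_exclusions_when_fraction_zero(self):
        spec = DEFAULT_SPEC.replace(n=400, excluded_fraction=0.0,
                                    missing_fraction=0.0)
        df = generate_cohort(spec, seed=1)
        assert not df["uses_gait_aid"].any()
        assert not df["needs_adl_iadl_assist"].any()
        assert df["pase_total"].notna().all()

    def test_sex_fraction_within_binomial_error(self):
        spec = DEFAULT_SPEC.replace(n=20000)
        df = generate_cohort(spec, seed=5)
        frac = (df["sex"] == "female").mean()
        se = np.sqrt(0.47 * 0.53 / len(df))
        assert abs(frac - 0.47) < 4 * se

    def test_ages_in_range_and_scores_nonnegative(self, small_cohort):
        assert small_cohort["age"].between(45, 85).all()
        assert (small_cohort["pase_total"].dropna() >= 0).all()

    def test_weighted_mean_matches_generator_expectation(self):
        """Included-subject weighted mean agrees with the closed-form mean
        of the generating distribution integrated over the age density."""
        spec = DEFAULT_SPEC.replace(n=50000, excluded_fraction=0.0,
                                    missing_fraction=0.0)
        df = generate_cohort(spec, seed=12)
        males = df[df["sex"] == "male"]
        w = males["inflation_weight"]
        got = float(np.sum(w * males["pase_total"]) / np.sum(w))

        fam = get_family(spec.male.family)
        pv0 = spec.male.params(45.0)
        ez, _ = integrate.quad(
            lambda z: z * float(fam.pdf(pv0.mu + pv0.sigma * pv0.tau * z, *pv0))
            * pv0.sigma * pv0.tau, -np.inf, np.inf, limit=300)
        # family mean at age a: mu(a) + sigma(a)*tau*E[z]
        a_lo, a_hi = (45 - spec.age_mean) / spec.age_sd, (85 - spec.age_mean) / spec.age_sd
        agepdf = stats.truncnorm(a_lo, a_hi, loc=spec.age_mean, scale=spec.age_sd).pdf

        def mean_at(a):
            pv = spec.male.params(a)
            return pv.mu + pv.sigma * pv.tau * ez

        want, _ = integrate.quad(lambda a: mean_at(a) * agepdf(a), 45, 85)
        se = males["pase_total"].std() / np.sqrt(len(males))
        assert got == pytest.approx(want, abs=5 * se + 0.5)


class TestApplyExclusions:
    def test_partition_covers_input(self, small_cohort):
        inc, exc, mis = apply_exclusions(small_cohort)
        assert len(inc) + len(exc) + len(mis) == len(small_cohort)
        assert set(inc.index).isdisjoint(exc.index)
        assert set(inc.index).isdisjoint(mis.index)
        assert set(exc.index).isdisjoint(mis.index)

    def test_gait_aid_excludes(self):
        df = pd.DataFrame({
            "uses_gait_aid": [True, False, False, np.nan],
            "needs_adl_iadl_assist": [False, False, np.nan, False],
            "pase_total": [100.0, 100.0, 100.0, 100.0]})
        inc, exc, mis = apply_exclusions(df)
        assert list(exc.index) == [0]
        assert list(inc.index) == [1]
        assert sorted(mis.index) == [2, 3]  # missing flags are routed, not guessed

    def test_missing_score_dropped(self):
        df = pd.DataFrame({
            "uses_gait_aid": [False], "needs_adl_iadl_assist": [False],
            "pase_total": [np.nan]})
        inc, exc, mis = apply_exclusions(df)
        assert len(inc) == 0 and len(exc) == 0 and len(mis) == 1


class TestAssignSeason:
    @pytest.mark.parametrize("d,season", [
        (date(2014, 2, 14), "winter"),
        (date(2014, 7, 1), "summer"),
        (date(2014, 12, 31), "fall"),
        (date(2014, 4, 1), "spring"),
        (date(2014, 3, 31), "winter"),
        (date(2014, 10, 1), "fall"),
    ])
    def test_month_mapping(self, d, season):
        assert assign_season(d) == season

    def test_total_over_all_months(self):
        seasons = {assign_season(date(2014, m, 15)) for m in range(1, 13)}
        assert seasons == set(ch.SEASONS)

    def test_invalid_date_rejected(self):
        with pytest.raises((ValueError, TypeError)):
            assign_season(float("nan"))

    def test_series_input(self, small_cohort):
        s = assign_season(small_cohort["interview_date"])
        assert s.isin(ch.SEASONS).all()


class TestWeightedDescriptives:
    def test_equal_weights_match_unweighted(self):
        df = pd.DataFrame({"age": [50.0, 60, 70], "pase_total": [100.0, 150, 200],
                           "inflation_weight": [2.0, 2, 2], "sex": "male"})
        out = weighted_descriptives(df)
        row = out[out["variable"] == "pase_total"].iloc[0]
        assert row["weighted_mean"] == pytest.approx(150.0)
        assert row["weighted_sd"] == pytest.approx(np.std([100, 150, 200]))

    def test_two_point_hand_value(self):
        df = pd.DataFrame({"pase_total": [100.0, 200.0],
                           "inflation_weight": [1.0, 3.0], "sex": "f"})
        out = weighted_descriptives(df, columns=("pase_total",))
        assert out.iloc[0]["weighted_mean"] == pytest.approx(175.0)

    def test_matches_replication_oracle(self, rng):
        """Integer weights equal physically replicating each record."""
        x = rng.normal(150, 40, size=40)
        w = rng.integers(1, 5, size=40).astype(float)
        df = pd.DataFrame({"pase_total": x, "inflation_weight": w, "sex": "m"})
        out = weighted_descriptives(df, columns=("pase_total",))
        expanded = np.repeat(x, w.astype(int))
        assert out.iloc[0]["weighted_mean"] == pytest.approx(expanded.mean())
        assert out.iloc[0]["weighted_sd"] == pytest.approx(expanded.std())

    def test_nonpositive_weights_rejected(self):
        df = pd.DataFrame({"pase_total": [1.0], "inflation_weight": [0.0],
                           "sex": "m"})
        with pytest.raises(ValueError, match="positive"):
            weighted_descriptives(df)


class TestCompareIncludedExcluded:
    def test_identical_groups_give_t_zero(self):
        g = pd.DataFrame({"age": [50.0] * 5, "pase_total": [1.0, 2, 3, 4, 5]})
        out = compare_included_excluded(g, g.copy(), bands=((45.0, 55.0),))
        assert out.iloc[0]["t"] == pytest.approx(0.0)

    def test_matches_hand_formula(self):
        a = pd.DataFrame({"age": [50.0] * 3, "pase_total": [1.0, 2, 3]})
        b = pd.DataFrame({"age": [50.0] * 3, "pase_total": [4.0, 5, 6]})
        out = compare_included_excluded(a, b, bands=((45.0, 55.0),))
        # Welch t for {1,2,3} vs {4,5,6}: diff -3, se = sqrt(1/3 + 1/3)
        want = -3.0 / np.sqrt(2.0 / 3.0)
        assert out.iloc[0]["t"] == pytest.approx(want)
        assert out.iloc[0]["mean_diff"] == pytest.approx(-3.0)

    def test_empty_band_flagged_skipped(self):
        a = pd.DataFrame({"age": [50.0, 51], "pase_total": [1.0, 2]})
        b = pd.DataFrame({"age": [80.0, 81], "pase_total": [1.0, 2]})
        out = compare_included_excluded(a, b, bands=((45.0, 55.0), (75.0, 86.0)))
        assert out["skipped"].tolist() == [True, True]

    def test_generator_effect_detected_in_all_bands(self):
        """With the default negative shift, every age band separates at
        the 0.001 level by n = 5,000."""
        df = generate_cohort(DEFAULT_SPEC.replace(n=5000, missing_fraction=0.0),
                             seed=21)
        inc, exc, _ = apply_exclusions(df)
        out = compare_included_excluded(inc, exc)
        assert not out["skipped"].any()
        assert (out["p"] < 0.001).all()
        assert (out["mean_diff"] > 0).all()  # included are more active


def test_true_centile_closed_form_matches_family():
    spec = DEFAULT_SPEC
    fam = get_family(spec.male.family)
    pv = spec.male.params(60.0)
    want = float(fam.quantile(0.5, *pv))
    assert true_centile(spec, "male", 60.0, 0.5) == pytest.approx(want)
    assert true_centile(spec, "male", 45.0, 0.5) - \
        true_centile(spec, "male", 85.0, 0.5) == pytest.approx(98.4, abs=1.0)
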