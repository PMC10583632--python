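"""Sub-model calibration: data subsetting, fitting and prediction."""

import warnings
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit
from scipy.stats import norm

import mauflow as mf
from mauflow.calibration import inpatient_day_table


def occ_series(counts, start=date(2017, 1, 1)):
    return mf.OccupancySeries(start, np.array(counts))


class TestLowOccupancySelection:
    @pytest.mark.parametrize(
        "counts, expected_retained",
        [
            ([1, 2, 3, 4, 5], 3),  # median 3: counts 1,2,3 kept
            ([2, 2, 2, 2], 4),  # all equal: everything kept
            ([0, 0, 10, 10], 2),  # median 5: the zero days kept
        ],
    )
    def test_median_rule(self, counts, expected_retained):
        retained = mf.select_low_occupancy_days(occ_series(counts))
        assert len(retained) == expected_retained

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=200))
    def test_at_least_half_retained(self, counts):
        retained = mf.select_low_occupancy_days(occ_series(counts))
        assert len(retained) >= len(counts) / 2

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            mf.select_low_occupancy_days(occ_series([]))


class TestAdmissionMean:
    def test_zero_coefficients(self):
        coeffs = mf.AdmissionCoefficients(0.0)
        assert mf.admission_mean(coeffs, date(2017, 6, 15)) == 0.0

    def test_additive_effects(self):
        coeffs = mf.AdmissionCoefficients(3.0, {"saturday": -0.8})
        saturday_jan = date(2017, 1, 7)
        assert mf.admission_mean(coeffs, saturday_jan) == pytest.approx(2.2)

    def test_negative_prediction_clamped(self):
        coeffs = mf.AdmissionCoefficients(0.1, {"sunday": -0.5})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert mf.admission_mean(coeffs, date(2017, 1, 1)) == 0.0  # a Sunday

    def test_invariant_to_date_shifts_preserving_weekday_and_month(self):
        coeffs = mf.AdmissionCoefficients(2.5, {"saturday": -0.7}, {"july": -0.4})
        a = mf.admission_mean(coeffs, date(2017, 7, 1))  # Saturday, July
        b = mf.admission_mean(coeffs, date(2023, 7, 8))  # Saturday, July
        assert a == b

    def test_reference_level_must_stay_implicit(self):
        with pytest.raises(ValueError):
            mf.AdmissionCoefficients(1.0, {"monday": 0.5})


class TestDischargeProbability:
    def test_zero_coefficients_give_half(self):
        assert mf.discharge_probability(mf.DischargeCoefficients(0.0), date(2017, 3, 3)) == 0.5

    def test_intercept_is_monday_probability(self):
        coeffs = mf.DischargeCoefficients(float(logit(0.3)))
        monday = date(2017, 1, 2)
        assert mf.discharge_probability(coeffs, monday) == pytest.approx(0.3)

    def test_large_negative_intercept_limit(self):
        coeffs = mf.DischargeCoefficients(-30.0)
        assert mf.discharge_probability(coeffs, date(2017, 1, 2)) < 1e-12


class TestAdmissionFit:
    def test_constant_admissions_recovered_exactly(self, stay_factory):
        start = date(2017, 1, 1)
        days = [start + timedelta(days=i) for i in range(120)]
        records = [
            stay_factory("u", d, d + timedelta(days=1)) for d in days for _ in range(2)
        ]
        coeffs = mf.fit_admission_model(records, days)
        assert coeffs.intercept == pytest.approx(2.0, abs=1e-9)
        for eff in {**coeffs.weekday_effects, **coeffs.month_effects}.values():
            assert eff == pytest.approx(0.0, abs=1e-9)

    def test_too_few_retained_days_fatal(self, stay_factory):
        days = [date(2017, 1, 1) + timedelta(days=i) for i in range(5)]
        records = [stay_factory("u", d, d + timedelta(days=1)) for d in days]
        with pytest.raises(ValueError, match="retained days"):
            mf.fit_admission_model(records, days)

    def test_parameter_recovery_from_known_truth(self):
        """Ten unconstrained years from beta0=3, Saturday -0.8, July -0.5
        put every named coefficient within 2 SE of truth (and none of the
        17 fitted coefficients grossly off)."""
        truth_adm = mf.AdmissionCoefficients(3.0, {"saturday": -0.8}, {"july": -0.5})
        truth_dis = mf.DischargeCoefficients(float(logit(1 / 3)))
        scenario = mf.make_scenario(
            units=[mf.UnitSpec("u", 40)],
            admission_coeffs={"u": truth_adm},
            discharge_coeffs={"u": truth_dis},
            years=10,
            seed=11,
            capacity_mode="unconstrained",
        )
        records, occ = mf.generate_records(scenario)
        fitted = mf.fit_admission_model(records, occ.dates)
        assert abs(fitted.intercept - 3.0) < 2 * fitted.intercept_se
        assert abs(fitted.weekday_effects["saturday"] + 0.8) < 2 * fitted.weekday_se["saturday"]
        assert abs(fitted.month_effects["july"] + 0.5) < 2 * fitted.month_se["july"]
        for name, est in fitted.weekday_effects.items():
            true = truth_adm.weekday_effects.get(name, 0.0)
            assert abs(est - true) < 3.5 * fitted.weekday_se[name]
        for name, est in fitted.month_effects.items():
            true = truth_adm.month_effects.get(name, 0.0)
            assert abs(est - true) < 3.5 * fitted.month_se[name]

    def test_null_effects_rarely_significant(self):
        """Intercept-only truth: weekday/month t-tests reject at the 5%
        level in only about 5% of (replicate, coefficient) pairs."""
        truth_adm = mf.AdmissionCoefficients(2.0)
        truth_dis = mf.DischargeCoefficients(float(logit(1 / 3)))
        pvals = []
        for seed in range(20):
            scenario = mf.make_scenario(
                units=[mf.UnitSpec("u", 30)],
                admission_coeffs={"u": truth_adm},
                discharge_coeffs={"u": truth_dis},
                years=2,
                seed=1000 + seed,
                capacity_mode="unconstrained",
            )
            records, occ = mf.generate_records(scenario)
            fitted = mf.fit_admission_model(records, occ.dates)
            for effects, ses in (
                (fitted.weekday_effects, fitted.weekday_se),
                (fitted.month_effects, fitted.month_se),
            ):
                for name, est in effects.items():
                    t = est / ses[name]
                    pvals.append(2 * (1 - norm.cdf(abs(t))))
        frac_nonsig = np.mean(np.array(pvals) > 0.05)
        assert frac_nonsig >= 0.90


class TestDischargeFit:
    def test_inpatient_day_expansion(self, stay_factory):
        # admitted Sun 2017-01-01, discharged Tue 2017-01-03: at-risk
        # midnights face Monday (not discharged) then Tuesday (discharged)
        rec = stay_factory("u", date(2017, 1, 1), date(2017, 1, 3))
        table = inpatient_day_table([rec])
        assert table["weekday"].tolist() == ["monday", "tuesday"]
        assert table["discharged"].tolist() == [0.0, 1.0]

    def test_constant_probability_recovered(self):
        truth_dis = mf.DischargeCoefficients(float(logit(1 / 3)))
        scenario = mf.make_scenario(
            units=[mf.UnitSpec("u", 30)],
            admission_coeffs={"u": mf.AdmissionCoefficients(3.0)},
            discharge_coeffs={"u": truth_dis},
            years=6,
            seed=5,
            capacity_mode="unconstrained",
        )
        records, _ = mf.generate_records(scenario)
        fitted = mf.fit_discharge_model(records)
        assert abs(fitted.intercept - logit(1 / 3)) < 2 * fitted.intercept_se
        for name, est in fitted.weekday_effects.items():
            assert abs(est) < 3.5 * fitted.weekday_se[name]

    def test_boosted_friday_probability_recovered(self):
        p_base, p_friday = 0.3, 0.6
        truth_dis = mf.DischargeCoefficients(
            float(logit(p_base)), {"friday": float(logit(p_friday) - logit(p_base))}
        )
        scenario = mf.make_scenario(
            units=[mf.UnitSpec("u", 30)],
            admission_coeffs={"u": mf.AdmissionCoefficients(3.0)},
            discharge_coeffs={"u": truth_dis},
            years=5,
            seed=3,
            capacity_mode="unconstrained",
        )
        records, _ = mf.generate_records(scenario)
        fitted = mf.fit_discharge_model(records)
        p_hat = expit(fitted.intercept + fitted.weekday_effects["friday"])
        n_friday = (inpatient_day_table(records)["weekday"] == "friday").sum()
        se_p = np.sqrt(p_friday * (1 - p_friday) / n_friday)
        assert abs(p_hat - p_friday) < 2 * se_p

    def test_all_one_night_stays_warn_of_separation(self, stay_factory):
        records = [
            stay_factory("u", date(2017, 1, 1) + timedelta(days=i), date(2017, 1, 2) + timedelta(days=i))
            for i in range(60)
        ]
        with pytest.warns(UserWarning, match="separation"):
            fitted = mf.fit_discharge_model(records)
        # implied probabilities pinned near 1, with huge uncertainty
        assert mf.discharge_probability(fitted, date(2017, 1, 2)) > 0.99

    def test_no_at_risk_midnights_fatal(self, stay_factory):
        records = [stay_factory("u", date(2017, 1, 1), date(2017, 1, 1))]
        with pytest.raises(ValueError):
            mf.fit_discharge_model(records)


class TestCoefficientFiles:
    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_round_trip(self, tmp_path, suffix):
        cs = mf.CoefficientSet(
            unit_id="mau1",
            admission=mf.AdmissionCoefficients(
                3.2, {"saturday": -0.8}, {"july": -0.5}, 0.1, {"saturday": 0.2}, {"july": 0.3}
            ),
            discharge=mf.DischargeCoefficients(-0.85, {"sunday": -0.4}, 0.05, {"sunday": 0.1}),
            bed_capacity=14,
        )
        path = tmp_path / f"coeffs{suffix}"
        mf.save_coefficients(cs, path)
        back = mf.load_coefficients(path)
        assert back == cs

    def test_reference_levels_never_stored(self, tmp_path):
        cs = mf.CoefficientSet(
            "u", mf.AdmissionCoefficients(1.0, {"tuesday": 0.1}), mf.DischargeCoefficients(0.0)
        )
        path = tmp_path / "coeffs.json"
        mf.save_coefficients(cs, path)
        text = path.read_text()
        assert "monday" not in text and "january" not in text
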