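"""Detector-vs-manual agreement: errors, MAE, concordance, age effects."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoscore import (
    OrganCounts,
    age_effect,
    age_error_difference,
    bin_errors_by_abundance,
    concordance,
    counting_errors,
    detection_ratio,
    mae_per_class,
    phenological_index,
)

from conftest import make_record


def ols_oracle(x, y):
    """Simple-regression slope/SE/intercept from the explicit sum formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy, sxy, sxx = x.sum(), y.sum(), (x * y).sum(), (x * x).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
    intercept = (sy - slope * sx) / n
    resid = y - intercept - slope * x
    s2 = (resid**2).sum() / (n - 2)
    se = math.sqrt(s2 / ((x - x.mean()) ** 2).sum())
    return slope, se, intercept


class TestCountingErrors:
    def test_sign_convention_predicted_minus_manual(self):
        rec = make_record(manual=(10, 0, 0, 0), predicted=(7, 2, 0, 0))
        err = counting_errors([rec])
        assert err.loc[0, "e_buds"] == -3        # under-count is negative
        assert err.loc[0, "e_flowers"] == 2      # over-count is positive

    def test_identity_gives_zero_errors(self):
        rec = make_record(manual=(4, 3, 2, 1), predicted=(4, 3, 2, 1))
        err = counting_errors([rec])
        assert (err.drop(columns="id") == 0).all().all()

    def test_missing_predicted_raises_with_id(self):
        with pytest.raises(ValueError, match="S1"):
            counting_errors([make_record(rid="S1")])


class TestMAE:
    @pytest.mark.parametrize(
        "errors, expected",
        [([-3, 1, 0], 4 / 3), ([0, 0, 0], 0.0), ([-2, -2, -2, -2], 2.0)],
    )
    def test_arithmetic(self, errors, expected):
        table = pd.DataFrame(
            {"id": range(len(errors)), **{f"e_{c}": errors for c in
             ("buds", "flowers", "immature_fruits", "mature_fruits")}}
        )
        assert mae_per_class(table)["buds"] == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mae_per_class(pd.DataFrame(columns=["id", "e_buds"]))

    def test_consistent_with_raw_count_columns(self):
        """MAE via the error table equals MAE computed from raw counts."""
        rng = np.random.default_rng(11)
        records = [
            make_record(rid=f"S{i}",
                        manual=tuple(rng.integers(0, 30, 4).tolist()),
                        predicted=tuple(rng.integers(0, 30, 4).tolist()))
            for i in range(40)
        ]
        via_errors = mae_per_class(counting_errors(records))
        man = np.array([r.manual_counts.as_tuple() for r in records])
        pred = np.array([r.predicted_counts.as_tuple() for r in records])
        direct = np.abs(pred - man).mean(axis=0)
        assert np.allclose(via_errors.to_numpy(), direct)


class TestConcordance:
    def _records(self, manual, predicted):
        return [make_record(rid=f"S{i}", manual=(m, 0, 0, 0), predicted=(p, 0, 0, 0))
                for i, (m, p) in enumerate(zip(manual, predicted))]

    def test_identity_gives_perfect_concordance(self):
        recs = self._records([1, 5, 9, 14], [1, 5, 9, 14])
        c = concordance(recs, "buds")
        assert c.pearson_r == pytest.approx(1.0)
        assert c.slope == pytest.approx(1.0)
        assert c.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_proportional_undercount(self):
        manual = [10, 20, 30, 40]
        predicted = [3, 6, 9, 12]  # exactly 0.3 x manual
        c = concordance(self._records(manual, predicted), "buds")
        assert c.pearson_r == pytest.approx(1.0)
        assert c.slope == pytest.approx(0.3)

    def test_five_point_toy_matches_sum_formula_oracle(self):
        manual = [2, 7, 11, 19, 25]
        predicted = [1, 3, 2, 6, 7]
        c = concordance(self._records(manual, predicted), "buds")
        slope, se, intercept = ols_oracle(manual, predicted)
        assert c.slope == pytest.approx(slope, abs=1e-10)
        assert c.slope_se == pytest.approx(se, abs=1e-10)
        assert c.intercept == pytest.approx(intercept, abs=1e-10)

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_oracle_on_random_instances(self, data):
        n = data.draw(st.integers(4, 20))
        manual = data.draw(
            st.lists(st.integers(0, 80), min_size=n, max_size=n)
            .filter(lambda xs: len(set(xs)) > 1)
        )
        predicted = data.draw(
            st.lists(st.integers(0, 80), min_size=n, max_size=n)
            .filter(lambda xs: len(set(xs)) > 1)
        )
        c = concordance(self._records(manual, predicted), "buds")
        slope, se, intercept = ols_oracle(manual, predicted)
        assert c.slope == pytest.approx(slope, abs=1e-9)
        assert c.intercept == pytest.approx(intercept, abs=1e-9)

    def test_degenerate_regressor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            concordance(self._records([5, 5, 5, 5], [1, 2, 3, 4]), "buds")

    def test_pi_target_uses_both_pi_estimates(self):
        recs = [make_record(rid=f"S{i}", manual=m, predicted=p) for i, (m, p) in
                enumerate([((10, 0, 0, 0), (3, 0, 0, 0)),
                           ((0, 10, 2, 0), (0, 3, 1, 0)),
                           ((0, 0, 5, 9), (0, 0, 2, 3)),
                           ((2, 4, 6, 8), (1, 1, 2, 2))])]
        c = concordance(recs, "pi")
        assert c.n == 4
        assert -1.0 <= c.pearson_r <= 1.0


class TestDetectionRatio:
    @pytest.mark.parametrize(
        "slope, printed",
        [(0.16, 6.2), (0.28, 3.6), (1.0, 1.0)],
    )
    def test_reciprocal_at_printed_precision(self, slope, printed):
        assert round(detection_ratio(slope), 1) == printed

    def test_raw_precision(self):
        assert detection_ratio(0.16) == pytest.approx(6.25)
        assert detection_ratio(0.28) == pytest.approx(1 / 0.28)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            detection_ratio(0.0)


class TestAbundanceBins:
    def test_bin_membership(self):
        recs = [make_record(rid=f"S{i}", manual=(m, 0, 0, 0), predicted=(m, 0, 0, 0))
                for i, m in enumerate([5, 15, 45])]
        bins = bin_errors_by_abundance(recs, "buds")
        assert [b.n for b in bins] == [1, 1, 0, 0, 1]
        assert bins[0].lower == 0 and bins[0].upper == 10
        assert math.isinf(bins[-1].upper)

    def test_perfect_detector_gives_zero_medians(self):
        rng = np.random.default_rng(5)
        recs = [make_record(rid=f"S{i}", manual=(int(m), 0, 0, 0), predicted=(int(m), 0, 0, 0))
                for i, m in enumerate(rng.integers(0, 60, 50))]
        for b in bin_errors_by_abundance(recs, "buds"):
            if b.n:
                assert b.median == 0

    def test_thinning_mean_error_tracks_bin_abundance(self):
        """Binomial thinning at p = 0.3: mean error ~ -0.7 x manual count."""
        rng = np.random.default_rng(99)
        manual = rng.integers(0, 50, 10_000)
        predicted = rng.binomial(manual, 0.3)
        recs = [make_record(rid=f"S{i}", manual=(int(m), 0, 0, 0), predicted=(int(p), 0, 0, 0))
                for i, (m, p) in enumerate(zip(manual, predicted))]
        bins = bin_errors_by_abundance(recs, "buds")
        err = predicted - manual
        for b in bins[:4]:
            sel = (manual >= b.lower) & (manual < b.upper)
            expected = -0.7 * manual[sel].mean()
            assert err[sel].mean() == pytest.approx(expected, abs=3 * 0.7 / np.sqrt(sel.sum()) * 5)


class TestAgeEffect:
    def test_constant_error_magnitude_gives_zero_slope(self):
        recs = [make_record(rid=f"S{i}", year=1900 + 5 * i,
                            manual=(10, 0, 0, 0), predicted=(8, 0, 0, 0))
                for i in range(10)]
        res = age_effect(recs, "buds")
        assert res.slope == 0.0

    def test_matches_transform_oracle_and_detects_age_growth(self):
        """Errors growing deterministically with age give a negative slope.

        The fitted slope must equal an independent polyfit of
        log10(|e| + 1) on year; errors built to roughly follow
        |e| + 1 = 10^(a (2000 - year)) with a = 0.002 recover a slope
        near -a and a clearly significant fit.
        """
        a = 0.01
        recs, years, errs = [], [], []
        for i, year in enumerate(range(1900, 2001, 4)):
            e = int(round(10 ** (a * (2000 - year)) - 1))
            m = max(e + 3, 5)
            recs.append(make_record(rid=f"S{i}", year=year,
                                    manual=(m, 0, 0, 0), predicted=(m - e, 0, 0, 0)))
            years.append(year)
            errs.append(e)
        res = age_effect(recs, "buds")
        oracle_slope = np.polyfit(np.asarray(years, float),
                                  np.log10(np.asarray(errs, float) + 1.0), 1)[0]
        assert res.slope == pytest.approx(oracle_slope, abs=1e-12)
        assert res.slope == pytest.approx(-a, rel=0.2)
        assert res.slope < 0 and res.p_value < 0.05

    def test_age_independent_errors_rarely_significant(self):
        """Null calibration: no age signal -> p > 0.05 in >= 90% of seeds."""
        nonsig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            recs = []
            for i in range(500):
                m = int(rng.integers(5, 40))
                p = int(rng.binomial(m, 0.25))
                recs.append(make_record(rid=f"S{i}", year=int(rng.integers(1900, 2014)),
                                        manual=(m, 0, 0, 0), predicted=(p, 0, 0, 0)))
            if age_effect(recs, "buds").p_value > 0.05:
                nonsig += 1
        assert nonsig >= 18

    def test_pi_response_uses_sqrt_transform(self, small_collection):
        res = age_effect(small_collection, "pi")
        assert res.transform == "sqrt"
        assert res.n <= len(small_collection)

    def test_constant_year_rejected(self):
        recs = [make_record(rid=f"S{i}", year=1950, predicted=(1, 1, 1, 1))
                for i in range(5)]
        with pytest.raises(ValueError, match="year"):
            age_effect(recs, "buds")

    def test_worked_error_difference(self):
        assert age_error_difference(-0.003, 100) == pytest.approx(0.3)


class TestThinningPreservesPI:
    def test_uniform_thinning_expected_counts_share_pi(self):
        counts = OrganCounts(12, 30, 9, 21)
        thinned = OrganCounts(*(c // 3 for c in counts.as_tuple()))  # p = 1/3 exact
        assert (phenological_index(thinned).value
                == pytest.approx(phenological_index(counts).value))

    def test_uniform_thinning_monte_carlo_pi_unbiased(self):
        """Same p for all classes leaves the PI unbiased.

        Class-blind thinning cannot shift composition systematically, so
        across 10^4 sheets (totals >= 40, p in [0.2, 0.8]) the mean signed
        PI drift stays within 0.05 of zero; individual sheets still
        scatter because few detected organs estimate composition noisily.
        """
        rng = np.random.default_rng(2021)
        n = 10_000
        manual = rng.multinomial(60, [0.3, 0.3, 0.2, 0.2], size=n)
        p = rng.uniform(0.2, 0.8, n)
        predicted = rng.binomial(manual, p[:, None])
        k = np.arange(1, 5)
        pi_man = (manual * k).sum(1) / manual.sum(1)
        tot = predicted.sum(1)
        ok = tot > 0
        pi_pred = (predicted[ok] * k).sum(1) / tot[ok]
        assert abs((pi_pred - pi_man[ok]).mean()) < 0.05
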