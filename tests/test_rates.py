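"""DOC*, stationary detection, rate fits, gates and growth efficiency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omrex import rates
from omrex.errors import (
    DegenerateDesignError,
    ImplausibleBiomassError,
    InsufficientDataError,
    NoGrowthError,
    UndefinedBGEError,
)


def test_doc_star_subtracts_biomass():
    assert rates.doc_star(59.6, 0.5) == pytest.approx(59.1)
    assert rates.doc_star(58.0, 0.0) == pytest.approx(58.0)
    with pytest.raises(ImplausibleBiomassError):
        rates.doc_star(58.0, 58.0)


class TestDetectStationary:
    def test_recovers_known_plateau(self):
        t = np.arange(0.0, 12.0)
        n = np.where(t < 7, 1e5 * np.exp(0.4 * t), 1e5 * np.exp(0.4 * 7))
        detected = rates.detect_stationary(t, n)
        assert abs(detected - 7.0) <= 1.0

    def test_pure_exponential_has_no_stationary(self):
        t = np.arange(0.0, 12.0)
        assert rates.detect_stationary(t, 1e5 * np.exp(0.3 * t)) is None

    @pytest.mark.parametrize(
        "series",
        [np.full(12, 5e5), 5e5 * np.exp(-0.2 * np.arange(12.0))],
        ids=["flat", "decline"],
    )
    def test_no_growth_raises(self, series):
        with pytest.raises(NoGrowthError):
            rates.detect_stationary(np.arange(12.0), series)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            rates.detect_stationary([0, 1, 2], [1, 2, 3])


class TestFitRate:
    def test_exact_lines(self):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        fit = rates.fit_rate(t, 58.0 - 0.2 * t)
        assert fit.slope == pytest.approx(-0.2, abs=1e-12)
        assert fit.magnitude == pytest.approx(0.2)
        assert fit.p_two_tailed < 1e-6
        t2 = np.arange(7.0)
        fit2 = rates.fit_rate(t2, 0.3 + 0.08 * t2)
        assert fit2.slope == pytest.approx(0.08, abs=1e-12)

    def test_matches_closed_form_ols(self, rng):
        """slope/se/p equal the textbook least-squares formulas."""
        from scipy import stats as ss

        for _ in range(200):
            n = rng.integers(3, 12)
            t = np.sort(rng.uniform(0, 10, n))
            if np.ptp(t) == 0:
                continue
            y = 58 - 0.2 * t + rng.normal(0, 0.7, n)
            fit = rates.fit_rate(t, y)
            sxx = np.sum((t - t.mean()) ** 2)
            slope = np.sum((t - t.mean()) * (y - y.mean())) / sxx
            intercept = y.mean() - slope * t.mean()
            resid = y - intercept - slope * t
            se = np.sqrt(np.sum(resid**2) / (n - 2) / sxx)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.slope_se == pytest.approx(se, abs=1e-10)
            if se > 0:
                p = 2 * ss.t.sf(abs(slope / se), n - 2)
                assert fit.p_two_tailed == pytest.approx(p, abs=1e-10)

    def test_degenerate_designs(self):
        with pytest.raises(InsufficientDataError):
            rates.fit_rate([0, 1], [1, 2])
        with pytest.raises(DegenerateDesignError):
            rates.fit_rate([1, 1, 1], [1, 2, 3])


class TestGates:
    @pytest.mark.parametrize(
        "delta,p_bp,p_doc,expected",
        [
            (1.3, 0.01, 0.01, False),  # below the 1.4 µmol C L⁻¹ drawdown gate
            (2.0, 0.01, 0.20, False),
            (2.0, 0.01, 0.01, True),
        ],
    )
    def test_examples(self, delta, p_bp, p_doc, expected):
        assert rates.resolvable(delta, p_bp, p_doc).overall is expected

    def test_default_gate_is_twice_precision(self):
        assert rates.DetectionGates().min_delta_doc == pytest.approx(1.4)

    def test_pure_conjunction(self):
        passing = dict(delta_doc=2.0, p_bp=0.01, p_doc=0.01)
        assert rates.resolvable(**passing).overall
        for fail in (
            dict(passing, delta_doc=1.0),
            dict(passing, p_bp=0.2),
            dict(passing, p_doc=0.2),
        ):
            assert not rates.resolvable(**fail).overall


class TestBGE:
    def test_reported_quotients(self):
        assert round(rates.bge(0.05, 0.11), 2) == pytest.approx(0.45)
        assert rates.bge(0.04, 0.16) == pytest.approx(0.25)
        assert rates.bge(0.2, 0.2) == pytest.approx(1.0)

    @given(
        bp=st.floats(0.01, 1.0),
        rate=st.floats(0.01, 1.0),
        k=st.floats(0.01, 100.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, bp, rate, k):
        assert rates.bge(k * bp, k * rate) == pytest.approx(
            rates.bge(bp, rate), rel=1e-9
        )

    def test_nonpositive_rates(self):
        with pytest.raises(UndefinedBGEError):
            rates.bge(0.0, 0.1)


class TestBGEError:
    def test_standard_propagation_reproduces_tabled_uncertainty(self):
        err = rates.bge_error(0.389, 0.18, 0.03, 0.07, 0.01, mode="standard")
        assert err == pytest.approx(0.085, abs=0.001)

    def test_literal_formula_cannot_reproduce_it(self):
        """The published formula inverts the ratios; evaluated literally it
        gives ~3.59, an order of magnitude above the tabled ±0.09."""
        err = rates.bge_error(0.389, 0.18, 0.03, 0.07, 0.01, mode="literal")
        assert err == pytest.approx(3.59, abs=0.01)
        assert err > 0.389  # always exceeds the BGE itself in this regime

    def test_zero_errors_give_zero(self):
        assert rates.bge_error(0.3, 0.2, 0.0, 0.06, 0.0) == 0.0

    def test_standard_below_bge_for_small_relative_errors(self, rng):
        for _ in range(50):
            rate, bp = rng.uniform(0.05, 0.5, 2)
            rate_se, bp_se = rate * rng.uniform(0, 0.5), bp * rng.uniform(0, 0.5)
            b = rates.bge(bp, rate)
            assert rates.bge_error(b, rate, rate_se, bp, bp_se) < b


class TestSummarize:
    def _frame(self):
        return pd.DataFrame(
            {
                "depth_m": [5, 5, 50],
                "treatment": ["diluted", "undiluted", "undiluted"],
                "short_rate": [0.2, 0.3, 0.1],
                "short_p": [0.01, 0.01, 0.5],
                "bp": [0.08, 0.1, 0.04],
                "bge": [0.3, np.nan, 0.2],
            }
        )

    def test_filters_on_significance(self):
        s = rates.summarize_experiments(self._frame())
        assert rates.summary_value(s, "short_rate", "all") == pytest.approx(0.25)
        assert rates.summary_value(s, "short_rate", "all", "n") == 2

    def test_singleton_sd_is_nan(self):
        s = rates.summarize_experiments(self._frame())
        assert np.isnan(rates.summary_value(s, "bge", "subsurface", "sd"))

    def test_empty_input(self):
        assert rates.summarize_experiments(pd.DataFrame()).empty
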