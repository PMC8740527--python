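"""ASV relative abundance, responders, diversity and indicator taxa."""

import math

import numpy as np
import pandas as pd
import pytest

from omrex import community
from omrex.errors import InsufficientDataError


class TestRelativeAbundance:
    def test_fractions(self):
        ra = community.relative_abundance(pd.Series([10, 30, 60]))
        assert np.allclose(ra, [0.1, 0.3, 0.6])
        assert community.relative_abundance(pd.Series([7]))[0] == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(InsufficientDataError):
            community.relative_abundance(pd.Series([0, 0]))


class TestTopN:
    def test_coverage(self):
        ra = pd.DataFrame(
            {"s1": [0.4, 0.3, 0.2, 0.07, 0.03]},
            index=[f"A{i}" for i in range(5)],
        )
        top, cov = community.top_n_asvs(ra, n=3)
        assert list(top) == ["A0", "A1", "A2"]
        assert cov["s1"] == pytest.approx(0.90)
        _, cov_all = community.top_n_asvs(ra, n=5)
        assert cov_all["s1"] == pytest.approx(1.0)

    def test_oversized_n_clips_with_warning(self):
        ra = pd.DataFrame({"s": [0.5, 0.5]}, index=["A", "B"])
        with pytest.warns(UserWarning):
            top, _ = community.top_n_asvs(ra, n=10)
        assert len(top) == 2


class TestRarefy:
    def test_preserves_depth_and_support(self, rng):
        counts = pd.Series(rng.integers(0, 200, 30))
        sub = community.rarefy(counts, 500, seed=1)
        assert sub.sum() == 500
        assert (sub <= counts).all()
        pd.testing.assert_series_equal(sub, community.rarefy(counts, 500, seed=1))

    def test_diversity_stable_under_rarefaction(self, rng):
        counts = pd.Series(rng.integers(0, 2000, 100))
        h_full = community.shannon(counts).H
        h_sub = community.shannon(community.rarefy(counts, 10000, seed=2)).H
        assert abs(h_full - h_sub) < 0.05

    def test_cannot_exceed_total(self):
        with pytest.raises(InsufficientDataError):
            community.rarefy(pd.Series([3, 2]), 100)


class TestLog2FoldChange:
    def test_threefold_is_responder(self):
        out = community.log2_fold_change(
            pd.Series({"a": 0.01}), pd.Series({"a": 0.03})
        )
        assert out.loc["a", "log2fc"] == pytest.approx(math.log2(3), abs=1e-9)
        assert bool(out.loc["a", "responder"])

    def test_equal_and_decreasing(self):
        out = community.log2_fold_change(
            pd.Series({"a": 0.02, "b": 0.04}), pd.Series({"a": 0.02, "b": 0.01})
        )
        assert out.loc["a", "log2fc"] == pytest.approx(0.0)
        assert out.loc["b", "log2fc"] == pytest.approx(-2.0)
        assert not out["responder"].any()

    def test_both_zero_is_na(self):
        out = community.log2_fold_change(pd.Series({"a": 0.0}), pd.Series({"a": 0.0}))
        assert np.isnan(out.loc["a", "log2fc"])
        assert not bool(out.loc["a", "responder"])

    def test_antisymmetry_with_symmetric_pseudocounts(self, rng):
        ra1 = pd.Series(rng.uniform(0, 0.1, 20))
        ra2 = pd.Series(rng.uniform(0, 0.1, 20))
        eps = 1e-4
        fwd = community.log2_fold_change(ra1, ra2, eps, eps)["log2fc"]
        rev = community.log2_fold_change(ra2, ra1, eps, eps)["log2fc"]
        assert np.allclose(fwd, -rev, atol=1e-9)


class TestShannon:
    def test_examples(self):
        assert community.shannon(pd.Series([42])).H == pytest.approx(0.0)
        assert community.shannon(pd.Series([5, 5, 5, 5])).H == pytest.approx(
            math.log(4), abs=1e-12
        )
        assert community.shannon(pd.Series([5, 3, 2])).H == pytest.approx(
            1.0297, abs=1e-4
        )

    def test_variance_formula(self):
        # hand evaluation for counts (5, 3, 2):
        # [Σ p ln²p − H²]/N + (S−1)/(2N²) = 0.0132965 + 0.01
        d = community.shannon(pd.Series([5, 3, 2]))
        assert d.variance == pytest.approx(0.0232965, abs=1e-6)
        lo, hi = d.ci95
        assert hi - lo == pytest.approx(2 * 1.96 * math.sqrt(d.variance), rel=1e-12)

    def test_maximal_at_uniformity_and_label_invariant(self, rng):
        counts = rng.integers(1, 100, 12)
        h = community.shannon(pd.Series(counts)).H
        assert 0.0 <= h <= math.log(12) + 1e-12
        h_perm = community.shannon(pd.Series(rng.permutation(counts))).H
        assert h == pytest.approx(h_perm, rel=1e-12)
        assert community.shannon(pd.Series([10] * 12)).H == pytest.approx(math.log(12))

    def test_against_independent_implementation(self, rng):
        from skbio.diversity.alpha import shannon as skbio_shannon

        counts = rng.integers(0, 500, 30)
        counts[0] = 5  # ensure nonzero
        assert community.shannon(pd.Series(counts)).H == pytest.approx(
            float(skbio_shannon(counts, base=math.e)), rel=1e-9
        )


class TestHutcheson:
    def test_identical_samples(self):
        d = community.shannon(pd.Series([50, 30, 20]))
        res = community.hutcheson_t(d, d)
        assert res["t"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        from scipy import stats as ss

        d1 = community.shannon(pd.Series([50, 30, 20]))
        d2 = community.shannon(pd.Series([90, 5, 5]))
        res = community.hutcheson_t(d1, d2)
        t = (d1.H - d2.H) / math.sqrt(d1.variance + d2.variance)
        df = (d1.variance + d2.variance) ** 2 / (
            d1.variance**2 / 100 + d2.variance**2 / 100
        )
        assert res["t"] == pytest.approx(t, abs=1e-9)
        assert res["df"] == pytest.approx(df, abs=1e-9)
        assert res["p"] == pytest.approx(2 * ss.t.sf(abs(t), df), abs=1e-9)

    def test_clear_difference_is_significant(self):
        d1 = community.shannon(pd.Series([400, 300, 300]))
        d2 = community.shannon(pd.Series([980, 10, 10]))
        assert community.hutcheson_t(d1, d2)["p"] < 0.01


class TestIndicatorRG:
    def test_exhaustive_two_plus_two(self):
        """Presence only in one 2-sample group: 2 of the 6 label
        arrangements reach |r.g| = 1, so p = 1/3."""
        ra = pd.DataFrame([[1.0, 1.0, 0.0, 0.0]], index=["a"],
                          columns=["s1", "s2", "s3", "s4"])
        res = community.indicator_rg(ra, ["A", "A", "B", "B"], group="A",
                                     method="exhaustive")
        assert res.loc[0, "rg_statistic"] == pytest.approx(1.0)
        assert res.loc[0, "permutation_p"] == pytest.approx(1 / 3)

    def test_constant_asv_is_na(self):
        ra = pd.DataFrame([[0.5, 0.5, 0.5, 0.5]], index=["a"],
                          columns=list("wxyz"))
        res = community.indicator_rg(ra, ["A", "A", "B", "B"], group="A",
                                     method="exhaustive")
        assert np.isnan(res.loc[0, "rg_statistic"])

    def test_perfect_indicator_with_equal_groups(self):
        ra = pd.DataFrame([[0.3, 0.31, 0.0, 0.0]], index=["a"],
                          columns=list("wxyz"))
        res = community.indicator_rg(ra, ["A", "A", "B", "B"], group="A",
                                     method="exhaustive")
        assert res.loc[0, "rg_statistic"] > 0.99

    def test_monte_carlo_approaches_exhaustive(self, rng):
        ra = pd.DataFrame(rng.uniform(0, 1, (5, 6)),
                          columns=[f"s{i}" for i in range(6)])
        labels = ["A", "A", "A", "B", "B", "B"]
        ex = community.indicator_rg(ra, labels, group="A", method="exhaustive")
        mc = community.indicator_rg(ra, labels, group="A", method="permutation",
                                    n_permutations=4999, seed=1)
        assert np.allclose(
            ex["permutation_p"], mc["permutation_p"], atol=0.05
        )

    def test_deterministic_under_seed(self, rng):
        ra = pd.DataFrame(rng.uniform(0, 1, (4, 10)),
                          columns=[f"s{i}" for i in range(10)])
        labels = ["A"] * 5 + ["B"] * 5
        a = community.indicator_rg(ra, labels, n_permutations=199, seed=42,
                                   method="permutation")
        b = community.indicator_rg(ra, labels, n_permutations=199, seed=42,
                                   method="permutation")
        pd.testing.assert_frame_equal(a, b)

    def test_pvalues_superuniform_under_null(self, rng):
        """On exchangeable data, small p-values are no more frequent than
        their nominal level."""
        n_asv = 200
        ra = pd.DataFrame(rng.lognormal(0, 1, (n_asv, 10)),
                          columns=[f"s{i}" for i in range(10)])
        labels = ["A"] * 5 + ["B"] * 5
        res = community.indicator_rg(ra, labels, group="A", n_permutations=199,
                                     seed=3, method="permutation")
        rate = (res["permutation_p"] <= 0.05).mean()
        assert rate <= 0.05 + 2.5 * math.sqrt(0.05 * 0.95 / n_asv)
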