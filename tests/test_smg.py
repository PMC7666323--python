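import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcprofiler.smg import (
    BackgroundModel,
    SmgModel,
    background_rate,
    call_smgs,
    differential_extract,
    estimate_pi0,
    gene_rate_test,
    storey_qvalues,
)

from _oracles import binom_tail_oracle

# ---------------------------------------------------------------------------


class TestBackgroundRate:
    def test_direct_arithmetic(self):
        bg = background_rate({"A": 3, "B": 7}, {"A": 1000, "B": 1000, "C": 2000})
        assert bg.total_mutations == 10
        assert bg.total_length_bp == 4000
        assert bg.rate_per_bp == pytest.approx(0.0025)

    def test_null_cohort_rate_zero(self):
        bg = background_rate({}, {"A": 1000})
        assert bg.rate_per_bp == 0.0

    def test_counted_gene_without_length_is_hard_error(self):
        with pytest.raises(ValueError, match="X"):
            background_rate({"X": 1}, {"A": 1000})

    def test_fifty_gene_fixture_matches_independent_tally(self, rng):
        genes = [f"G{i}" for i in range(50)]
        lengths = {g: int(rng.integers(300, 5000)) for g in genes}
        counts = {g: int(rng.poisson(2)) for g in genes[:30]}
        bg = background_rate(counts, lengths)
        # independent tally over the raw dictionaries
        assert bg.rate_per_bp == pytest.approx(
            sum(counts.values()) / sum(lengths.values()), rel=1e-15
        )


class TestGeneRateTest:
    BG = BackgroundModel(total_mutations=100, total_length_bp=1_000_000)

    def test_zero_count_gives_p_one_for_both_methods(self):
        for method in ("conditional_exact", "poisson_tail"):
            assert gene_rate_test(0, 1000, self.BG, method=method) == 1.0

    def test_poisson_example_closed_form(self):
        # e = 0.1; P(X >= 3) = 1 - e^{-0.1} (1 + 0.1 + 0.005)
        expected = 1.0 - math.exp(-0.1) * (1 + 0.1 + 0.1**2 / 2)
        p = gene_rate_test(3, 1000, self.BG, method="poisson_tail")
        assert p == pytest.approx(expected, rel=1e-12)

    def test_conditional_exact_matches_binomial_summation(self):
        p = gene_rate_test(3, 1000, self.BG, method="conditional_exact")
        assert p == pytest.approx(binom_tail_oracle(3, 100, 0.001), rel=1e-12)

    def test_monotone_nonincreasing_in_observed_count(self):
        for method in ("conditional_exact", "poisson_tail"):
            ps = [gene_rate_test(x, 2000, self.BG, method=method) for x in range(12)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_methods_agree_in_poisson_limit(self):
        """Binomial -> Poisson for small gene share and many events."""
        bg = BackgroundModel(total_mutations=20_000, total_length_bp=40_000_000)
        for length in (500, 1000, 2000):  # e_g = 0.25 .. 1.0
            for x in (1, 2, 3, 5):
                pc = gene_rate_test(x, length, bg, method="conditional_exact")
                pp = gene_rate_test(x, length, bg, method="poisson_tail")
                assert pc == pytest.approx(pp, rel=0.10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            gene_rate_test(-1, 1000, self.BG)
        with pytest.raises(ValueError):
            gene_rate_test(1, 0, self.BG)
        with pytest.raises(ValueError):
            gene_rate_test(1, 2_000_000, self.BG)
        with pytest.raises(ValueError):
            gene_rate_test(101, 1000, self.BG)


class TestStorey:
    def test_single_p_of_one(self):
        assert storey_qvalues([1.0]) == pytest.approx([1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])

    def test_qvalues_monotone_in_p_order(self, rng):
        p = rng.uniform(size=500)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.permutations(list(range(12))))
    def test_permutation_equivariance(self, perm):
        p = np.linspace(0.01, 0.9, 12)
        q = storey_qvalues(p)
        q_perm = storey_qvalues(p[perm])
        assert np.allclose(q_perm, q[perm])

    def test_pi0_unbiased_on_uniform_null(self):
        vals = [
            estimate_pi0(np.random.default_rng(s).uniform(size=2000))
            for s in range(20)
        ]
        assert 0.9 <= np.mean(vals) <= 1.1

    def test_planted_signals_get_small_q(self):
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(1e-10, 1e-6, 200), rng.uniform(size=1800)])
        q = storey_qvalues(p)
        assert q[:200].mean() <= 0.05


class TestCalls:
    def _frame(self, p, q, tested):
        return pd.DataFrame(
            {"p_value": [p], "q_value": [q], "tested": [tested]}, index=["G"]
        )

    @pytest.mark.parametrize(
        "p,q,tested,expected",
        [
            (0.005, 0.20, True, True),
            (0.005, 0.30, True, False),
            (0.005, 0.20, False, False),  # observed <= expected gate
            (0.02, 0.10, True, False),
        ],
    )
    def test_threshold_logic(self, p, q, tested, expected):
        out = call_smgs(self._frame(p, q, tested))
        assert bool(out["significant"].iloc[0]) is expected


def _results_frame(rows):
    frame = pd.DataFrame(rows).set_index("gene")
    return frame


class TestDifferential:
    def test_printed_driver_pvalues_retained_at_both_folds(self):
        """CDH1/RHOA printed p-value pairs pass fold 10; CDH1 passes fold 100."""
        target = _results_frame(
            [
                {"gene": "CDH1", "p_value": 2.74e-26, "significant": True},
                {"gene": "RHOA", "p_value": 5.42e-17, "significant": True},
            ]
        )
        counter = _results_frame(
            [
                {"gene": "CDH1", "p_value": 0.3696, "significant": False},
                {"gene": "RHOA", "p_value": 0.0416, "significant": False},
            ]
        )
        d10 = differential_extract(target, counter, fold=10)
        assert list(d10.index) == ["CDH1", "RHOA"]
        assert d10.loc["CDH1", "log10_ratio"] == pytest.approx(25.13, abs=0.01)
        d100 = differential_extract(target, counter, fold=100)
        assert "CDH1" in d100.index and "RHOA" in d100.index

    def test_small_ratio_excluded(self):
        t = _results_frame([{"gene": "G", "p_value": 1e-3, "significant": True}])
        c = _results_frame([{"gene": "G", "p_value": 5e-3, "significant": False}])
        assert differential_extract(t, c, fold=10).empty

    def test_equal_pvalues_excluded(self):
        t = _results_frame([{"gene": "G", "p_value": 1e-3, "significant": True}])
        c = _results_frame([{"gene": "G", "p_value": 1e-3, "significant": False}])
        out = differential_extract(t, c, fold=10)
        assert out.empty

    def test_extraction_is_antisymmetric(self, rng):
        genes = [f"G{i}" for i in range(40)]
        pa = rng.uniform(1e-8, 1, size=40)
        pb = rng.uniform(1e-8, 1, size=40)
        a = _results_frame(
            [{"gene": g, "p_value": p, "significant": True} for g, p in zip(genes, pa)]
        )
        b = _results_frame(
            [{"gene": g, "p_value": p, "significant": True} for g, p in zip(genes, pb)]
        )
        ab = set(differential_extract(a, b, fold=10).index)
        ba = set(differential_extract(b, a, fold=10).index)
        assert not ab & ba

    def test_missing_counterpart_is_error(self):
        t = _results_frame([{"gene": "G", "p_value": 1e-3, "significant": True}])
        c = _results_frame([{"gene": "H", "p_value": 0.5, "significant": False}])
        with pytest.raises(ValueError, match="counterpart"):
            differential_extract(t, c)


class TestSmgModel:
    def test_fit_scores_all_genes_in_length_table(self):
        res = SmgModel({"A": 8}, {"A": 1000, "B": 1000, "C": 2000}).fit()
        assert list(res.frame.index) == ["A", "B", "C"]
        assert res.frame.loc["B", "observed"] == 0
        assert res.frame.loc["B", "p_value"] == 1.0
        assert bool(res.frame.loc["A", "significant"])
        # expected = rate * length to near machine precision
        bg = res.background
        expect = res.frame["length_bp"] * bg.rate_per_bp
        assert np.allclose(res.frame["expected"], expect, rtol=1e-12)

    def test_summary_mentions_background_and_counts(self):
        res = SmgModel({"A": 8}, {"A": 1000, "B": 3000}).fit()
        text = res.summary()
        assert "background rate" in text
        assert "significant genes" in text
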