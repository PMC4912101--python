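import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from alupopdiv import (
    GenotypeCounts,
    MonomorphicLocusError,
    PopulationDiversity,
    SimulationConfig,
    allele_frequency,
    average_heterozygosity,
    bonferroni_adjust,
    expected_heterozygosity,
    hwe_test,
    observed_heterozygosity,
    simulate_genotypes,
)

counts_strategy = st.tuples(
    st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
).filter(lambda c: sum(c) > 0)


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((50, 0, 0), 1.0),  # fixed for the insertion
            ((10, 20, 20), 0.40),  # (2*10 + 20) / 100
            ((0, 0, 7), 0.0),
            ((3, 11, 3), 0.5),  # symmetric counts
        ],
    )
    def test_direct_counting(self, counts, expected):
        f = allele_frequency(GenotypeCounts(*counts))
        assert f.p == pytest.approx(expected)
        assert f.p + f.q == pytest.approx(1.0)

    def test_empty_cell_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            allele_frequency(GenotypeCounts(0, 0, 0))

    @settings(max_examples=50, derandomize=True)
    @given(counts_strategy)
    def test_matches_allele_list_expansion(self, counts):
        # each II contributes two insertion alleles, each ID one
        n_ii, n_id, n_dd = counts
        alleles = [1] * (2 * n_ii + n_id) + [0] * (n_id + 2 * n_dd)
        assert allele_frequency(GenotypeCounts(*counts)).p == pytest.approx(np.mean(alleles))


class TestHeterozygosity:
    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_monomorphic_has_no_heterozygosity(self, p):
        assert expected_heterozygosity(p) == 0.0

    def test_maximal_at_half(self):
        assert expected_heterozygosity(0.5) == pytest.approx(0.5)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.0, 1.0))
    def test_symmetric_under_allele_swap(self, p):
        assert expected_heterozygosity(p) == pytest.approx(expected_heterozygosity(1 - p))
        assert 0.0 <= expected_heterozygosity(p) <= 0.5

    @pytest.mark.parametrize(
        "counts, expected", [((1, 2, 1), 0.5), ((0, 0, 10), 0.0), ((5, 0, 0), 0.0)]
    )
    def test_observed_proportion(self, counts, expected):
        assert observed_heterozygosity(GenotypeCounts(*counts)) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(counts_strategy)
    def test_observed_matches_tally(self, counts):
        calls = ["II"] * counts[0] + ["ID"] * counts[1] + ["DD"] * counts[2]
        assert observed_heterozygosity(GenotypeCounts(*counts)) == pytest.approx(
            calls.count("ID") / len(calls)
        )

    def test_average_single_locus_identity(self):
        assert average_heterozygosity([0.37]) == pytest.approx(0.37)

    def test_average_empty_is_error(self):
        with pytest.raises(ValueError):
            average_heterozygosity([])

    def test_mean_observed_approaches_2pq_under_hwe(self, rng):
        # large HWE sample: h_obs concentrates on 2pq
        p = 0.3
        counts = rng.multinomial(20_000, [p * p, 2 * p * (1 - p), (1 - p) ** 2])
        h = observed_heterozygosity(GenotypeCounts(*counts))
        assert h == pytest.approx(2 * p * (1 - p), abs=0.01)


class TestHweTest:
    def test_exact_proportions_give_zero(self):
        res = hwe_test(GenotypeCounts(25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # p_hat = 0.5, expected (25, 50, 25), chi2 = 1 + 2 + 1 = 4
        res = hwe_test(GenotypeCounts(30, 40, 30))
        assert res.chi2 == pytest.approx(4.0, abs=1e-12)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(4.0, 1))
        assert res.p_value == pytest.approx(0.0455, abs=5e-4)

    def test_monomorphic_cell_flagged(self):
        with pytest.raises(MonomorphicLocusError):
            hwe_test(GenotypeCounts(40, 0, 0))

    @settings(max_examples=50, derandomize=True)
    @given(counts_strategy.filter(lambda c: 0 < 2 * c[0] + c[1] < 2 * sum(c)))
    def test_matches_brute_force_goodness_of_fit(self, counts):
        n = sum(counts)
        p = (2 * counts[0] + counts[1]) / (2 * n)
        expected = [n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)]
        oracle = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
        assert hwe_test(GenotypeCounts(*counts)).chi2 == pytest.approx(oracle, rel=1e-12)

    def test_family_size_adjusts_p(self):
        res = hwe_test(GenotypeCounts(30, 40, 30), m=10)
        assert res.p_adjusted == pytest.approx(min(1.0, 10 * res.p_value))


class TestBonferroni:
    @pytest.mark.parametrize(
        "p_in, expected",
        [([0.01], [0.01]), ([0.01, 0.5], [0.02, 1.0])],
    )
    def test_examples(self, p_in, expected):
        assert bonferroni_adjust(p_in) == pytest.approx(expected)

    def test_full_survey_family(self):
        # 12 populations x 7 loci tested together
        p = [0.0005] + [0.5] * 83
        assert bonferroni_adjust(p)[0] == pytest.approx(84 * 0.0005)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5, 1.2])


class TestPopulationDiversity:
    def test_summary_layout_and_counting(self, small_table):
        est = PopulationDiversity().fit(small_table)
        assert est.het_observed_.loc["A", "ACE"] == pytest.approx(0.5)  # 2 ID of 4
        out = est.summary()
        assert "All loci" in out.columns
        assert out.loc["A", "All loci"] == pytest.approx(
            np.mean([est.het_observed_.loc["A", "ACE"], est.het_observed_.loc["A", "TPA25"]])
        )

    def test_expected_series_selectable(self, small_table):
        est = PopulationDiversity(het="expected").fit(small_table)
        p = est.frequencies_.p.loc["A", "ACE"]
        assert est.summary().loc["A", "ACE"] == pytest.approx(2 * p * (1 - p))

    def test_hwe_report_family_and_monomorphic_flags(self, small_table):
        est = PopulationDiversity().fit(small_table)
        # B/ACE is fixed for the deletion: flagged, not tested
        assert ("B", "ACE") in est.monomorphic_
        assert (est.hwe_["m"] == len(est.hwe_)).all()
        assert (est.hwe_["p_adjusted"] >= est.hwe_["p_value"] - 1e-15).all()

    def test_on_simulated_dataset(self, sim_dataset):
        est = PopulationDiversity().fit(sim_dataset.genotypes)
        counts = sim_dataset.counts
        phat = (2 * counts[..., 0] + counts[..., 1]) / (2 * counts.sum(axis=2))
        np.testing.assert_allclose(est.frequencies_.to_numpy(), phat)

    def test_sklearn_param_contract(self):
        est = PopulationDiversity(het="expected", hwe_family="per-locus")
        assert est.get_params() == {"het": "expected", "hwe_family": "per-locus"}
        est.set_params(het="observed")
        assert est.het == "observed"
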