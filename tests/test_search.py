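import math
from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgcp.genotype_io import GenotypeFrequencies
from cgcp.search import (CandidateCGCP, GenotypePattern, PrevalenceModel,
                         SearchConfig, brute_force_search,
                         candidates_to_frame, count_pattern_space,
                         enumerate_observed_patterns,
                         pattern_product_frequency, population_frequency,
                         search_cgcp, summarize_frequency_distribution)
from cgcp.simulate import PlantSpec, SimulationConfig, simulate_cohort
from conftest import matrices_from_codes, random_cohort

WIDE = PrevalenceModel(p=0.5, lower_mult=1e-9, upper_mult=1.0)


class TestPatternSpace:
    def test_matches_explicit_enumeration(self):
        # oracle: literally list every (SNP subset, genotype tuple) pair
        for n in range(7):
            for r in range(n + 1):
                explicit = sum(1 for _ in combinations(range(n), r)
                               for _ in product((0, 1, 2), repeat=r))
                assert count_pattern_space(n, r) == explicit

    @pytest.mark.parametrize("n,r,expected", [
        (2, 1, 6), (3, 2, 27), (51, 3, 562_275),
    ])
    def test_known_values(self, n, r, expected):
        result = count_pattern_space(n, r)
        assert result == expected
        assert isinstance(result, int)

    def test_r_above_n_rejected(self):
        with pytest.raises(ValueError):
            count_pattern_space(3, 4)


class TestPopulationFrequency:
    def test_fixed_point_when_cohorts_agree(self):
        for p in (0.0047, 0.3, 0.9):
            model = PrevalenceModel(p)
            assert population_frequency(0.2, 0.2, model) == \
                pytest.approx(0.2, abs=1e-15)

    def test_arithmetic_mean_at_lambda_one(self):
        model = PrevalenceModel(0.5)
        assert model.lam == pytest.approx(1.0)
        assert population_frequency(0.3, 0.1, model) == pytest.approx(0.2)

    def test_hand_computed_low_prevalence(self):
        # lambda = 0.9953/0.0047; F = (0.5 + lambda*0.1) / (1 + lambda)
        model = PrevalenceModel(0.0047)
        lam = 0.9953 / 0.0047
        expected = (0.5 + lam * 0.1) / (1 + lam)
        assert model.lam == pytest.approx(lam, abs=1e-12)
        assert population_frequency(0.5, 0.1, model) == \
            pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        model = PrevalenceModel(0.1)
        with pytest.raises(ValueError):
            population_frequency(-0.1, 0.5, model)
        with pytest.raises(ValueError):
            population_frequency(0.5, 1.2, model)

    @given(st.floats(0, 1), st.floats(0, 1),
           st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_inputs(self, alpha, beta, p):
        f = population_frequency(alpha, beta, PrevalenceModel(p))
        assert min(alpha, beta) - 1e-12 <= f <= max(alpha, beta) + 1e-12


class TestProductFrequency:
    def _freqs(self):
        alpha = np.array([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3], [0.25, 0.5, 0.25]])
        beta = np.array([[0.4, 0.4, 0.2], [0.2, 0.5, 0.3], [0.3, 0.4, 0.3]])
        return GenotypeFrequencies(alpha, beta)

    def test_single_snp_reduces_to_population_frequency(self):
        freqs = self._freqs()
        model = PrevalenceModel(0.1)
        pat = GenotypePattern((1,), (2,))
        assert pattern_product_frequency(pat, freqs, model) == \
            pytest.approx(population_frequency(0.3, 0.3, model))

    def test_product_law(self):
        alpha = np.array([[0.1, 0.8, 0.1], [0.1, 0.8, 0.1]])
        freqs = GenotypeFrequencies(alpha, alpha.copy())
        model = PrevalenceModel(0.2)
        pat = GenotypePattern((0, 1), (0, 0))
        assert pattern_product_frequency(pat, freqs, model) == \
            pytest.approx(0.01)

    def test_three_snp_hand_product(self):
        freqs = self._freqs()
        model = PrevalenceModel(0.25)  # lambda = 3
        pat = GenotypePattern((0, 1, 2), (0, 1, 2))
        hand = ((0.5 + 3 * 0.4) / 4) * ((0.6 + 3 * 0.5) / 4) \
            * ((0.25 + 3 * 0.3) / 4)
        assert pattern_product_frequency(pat, freqs, model) == \
            pytest.approx(hand, abs=1e-12)


class TestEnumerateObserved:
    def test_single_sample_tuple(self):
        cases, _ = matrices_from_codes([[0, 2]], [[1, 1]])
        observed = enumerate_observed_patterns(cases, (0, 1))
        assert observed == {(0, 2): ["case_0"]}

    def test_missing_call_excludes_sample(self):
        cases, _ = matrices_from_codes([[0, -1]], [[1, 1]])
        assert enumerate_observed_patterns(cases, (0, 1)) == {}

    def test_hand_enumeration_eight_samples(self):
        rows = [[0, 0], [0, 0], [0, 1], [1, 2],
                [1, 2], [2, 2], [0, -1], [1, 2]]
        cases, _ = matrices_from_codes(rows, [[0, 0]])
        observed = enumerate_observed_patterns(cases, (0, 1))
        assert observed == {
            (0, 0): ["case_0", "case_1"],
            (0, 1): ["case_2"],
            (1, 2): ["case_3", "case_4", "case_7"],
            (2, 2): ["case_5"],
        }


class TestSearch:
    def test_single_control_occurrence_eliminates(self):
        case_rows = [[0, 0]] * 10
        ctrl_rows = [[0, 0]] + [[2, 2]] * 9
        cases, controls = matrices_from_codes(case_rows, ctrl_rows)
        config = SearchConfig(r=2, min_carriers=1, prevalence_model=WIDE)
        results = search_cgcp(cases, controls, config)
        assert (0, 0) not in [c.pattern.genotype_codes for c in results
                              if c.pattern.snp_indices == (0, 1)]

    def test_planted_pattern_recovered(self):
        model = PrevalenceModel(0.0047)
        config = SimulationConfig(
            n_snps=12, n_cases=300, n_controls=300, seed=9,
            missing_rate=0.0,
            planted_patterns=[PlantSpec(3, 10, (model.lower_bound,
                                                model.upper_bound))])
        cases, controls, _, truth = simulate_cohort(config)
        results = search_cgcp(cases, controls, SearchConfig(
            r=3, min_carriers=8, prevalence_model=model))
        planted = truth.patterns[0]
        match = [c for c in results if c.pattern == planted.pattern]
        assert len(match) == 1
        assert set(match[0].case_carriers) >= set(planted.carrier_ids)

    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_equals_brute_force_oracle(self, r):
        rng = np.random.default_rng(100 + r)
        cases, controls = random_cohort(rng, 10, 50, 50)
        config = SearchConfig(r=r, min_carriers=2, prevalence_model=WIDE)
        fast = search_cgcp(cases, controls, config)
        slow = brute_force_search(cases, controls, config)
        assert [(c.pattern, c.case_carriers) for c in fast] == \
            [(c.pattern, c.case_carriers) for c in slow]
        for a, b in zip(fast, slow):
            assert a.product_frequency == pytest.approx(b.product_frequency,
                                                        abs=1e-12)

    def test_case_exclusivity_rescan(self):
        rng = np.random.default_rng(3)
        cases, controls = random_cohort(rng, 8, 80, 80)
        config = SearchConfig(r=2, min_carriers=1, prevalence_model=WIDE)
        for cand in search_cgcp(cases, controls, config):
            sub = controls.calls[:, list(cand.pattern.snp_indices)]
            arr = np.array(cand.pattern.genotype_codes, dtype=np.int8)
            assert not (sub == arr).all(axis=1).any()

    def test_bound_compliance(self):
        rng = np.random.default_rng(4)
        cases, controls = random_cohort(rng, 8, 60, 60)
        model = PrevalenceModel(0.3, 0.2, 0.8)
        config = SearchConfig(r=2, min_carriers=1, prevalence_model=model)
        results = search_cgcp(cases, controls, config)
        for cand in results:
            assert model.lower_bound < cand.product_frequency \
                < model.upper_bound

    def test_min_carriers_monotonicity(self):
        rng = np.random.default_rng(6)
        cases, controls = random_cohort(rng, 8, 80, 80)
        base = None
        for mc in (1, 3, 6):
            config = SearchConfig(r=2, min_carriers=mc, prevalence_model=WIDE)
            patterns = {c.pattern for c in
                        search_cgcp(cases, controls, config)}
            if base is not None:
                assert patterns <= base
            base = patterns

    def test_deterministic_sorted_output(self):
        rng = np.random.default_rng(8)
        cases, controls = random_cohort(rng, 8, 60, 60)
        config = SearchConfig(r=2, min_carriers=1, prevalence_model=WIDE)
        a = search_cgcp(cases, controls, config)
        b = search_cgcp(cases, controls, config)
        assert [(c.pattern, c.case_carriers, c.product_frequency)
                for c in a] == \
            [(c.pattern, c.case_carriers, c.product_frequency) for c in b]
        counts = [c.n_case_carriers for c in a]
        assert counts == sorted(counts, reverse=True)

    def test_r_exceeding_snps_rejected(self):
        cases, controls = matrices_from_codes([[0, 1]], [[1, 1]])
        with pytest.raises(ValueError):
            search_cgcp(cases, controls,
                        SearchConfig(r=3, min_carriers=1,
                                     prevalence_model=WIDE))

    def test_brute_force_guard(self):
        rng = np.random.default_rng(9)
        cases, controls = random_cohort(rng, 20, 10, 10)
        config = SearchConfig(r=5, min_carriers=1, prevalence_model=WIDE)
        # 3^5 * C(20,5) ~ 3.8M exceeds the 1e6 guard
        with pytest.raises(ValueError, match="guard"):
            brute_force_search(cases, controls, config)

    def test_brute_force_single_snp_exclusive(self):
        cases, controls = matrices_from_codes([[0]], [[1]])
        config = SearchConfig(r=1, min_carriers=1, prevalence_model=WIDE,
                              apply_bounds=False)
        results = brute_force_search(cases, controls, config)
        assert [c.pattern for c in results] == [GenotypePattern((0,), (0,))]


class TestFrequencySummary:
    def _cand(self, f):
        return CandidateCGCP(GenotypePattern((0,), (0,)), ["s"], f)

    def test_single_candidate(self):
        s = summarize_frequency_distribution([self._cand(0.004)])
        assert s.mean == s.min == s.max == 0.004
        assert s.sd == 0.0

    def test_two_candidates_mean(self):
        s = summarize_frequency_distribution(
            [self._cand(0.0001), self._cand(0.0003)])
        assert s.mean == pytest.approx(0.0002)

    def test_empty_sentinel(self):
        s = summarize_frequency_distribution([])
        assert s.count == 0 and s.mean is None


class TestCandidateTable:
    def test_genotype_string_rendering(self):
        cases, controls = matrices_from_codes([[0, 1, 2]] * 3, [[2, 0, 0]])
        config = SearchConfig(r=3, min_carriers=3, prevalence_model=WIDE)
        results = search_cgcp(cases, controls, config)
        frame = candidates_to_frame(results, cases.snps)
        row = frame[frame.n_case_carriers == 3].iloc[0]
        # alleles are A/C throughout; codes (0,1,2) -> AA, AC, CC
        assert row.genotype_string == "AAACCC"
        assert row.rsid_1 == "rs00000"
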