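"""Expression normalization, delta-IR integration, and set statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retentio.ir_core import DifferentialIREvent
from retentio.integration_stats import (
    gene_mean_delta_ir,
    grouped_lfc_comparison,
    gsea_preranked,
    integrate,
    median_of_ratios_size_factors,
    normalize_and_lfc,
    overlap_test,
    set_enrichment,
    threeway_overlap_test,
    _enrichment_score,
)


def _event(intron_id, gene_id, delta, p=0.01):
    return DifferentialIREvent(
        intron_id, gene_id, ("A", "B"), 1, 1, 1, 1,
        0.5, 0.5 - delta, delta, p, p < 0.05,
    )


class TestNormalizeAndLFC:
    def test_identical_samples_are_null(self):
        counts = pd.DataFrame(
            {"a1": [100, 50, 10], "a2": [100, 50, 10],
             "b1": [100, 50, 10], "b2": [100, 50, 10]},
            index=["g1", "g2", "g3"],
        )
        factors = median_of_ratios_size_factors(counts)
        assert np.allclose(factors, 1.0)
        result = normalize_and_lfc(counts, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(result["log2fc"], 0.0)

    def test_doubled_gene_recovers_unit_lfc(self):
        rng = np.random.default_rng(0)
        base = rng.integers(200, 2000, size=200)
        counts = pd.DataFrame(
            {
                "a1": base, "a2": base,
                "b1": base, "b2": base,
            },
            index=[f"g{i}" for i in range(200)],
        )
        counts.loc["g0", ["a1", "a2"]] = base[0] * 2
        result = normalize_and_lfc(counts, ["a1", "a2"], ["b1", "b2"])
        lfc = result.set_index("gene_id").loc["g0", "log2fc"]
        assert lfc == pytest.approx(1.0, abs=0.1)

    def test_all_zero_genes_excluded(self):
        counts = pd.DataFrame(
            {"a1": [10, 0], "b1": [20, 0]}, index=["g1", "g2"]
        )
        result = normalize_and_lfc(counts, ["a1"], ["b1"])
        assert list(result["gene_id"]) == ["g1"]


class TestGeneMeanDeltaIR:
    @pytest.mark.parametrize(
        "deltas, lengths, expected",
        [
            ([-0.2], [500], -0.2),
            ([-0.1, -0.3], [100, 300], -0.25),
            ([-0.1, -0.3], [200, 200], -0.2),  # equal lengths = plain mean
        ],
    )
    def test_length_weighting(self, deltas, lengths, expected):
        assert gene_mean_delta_ir(deltas, lengths) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_mean_delta_ir([], [])


class TestIntegrate:
    def _expression(self, lfcs):
        return pd.DataFrame(
            {"gene_id": list(lfcs), "log2fc": list(lfcs.values())}
        )

    def test_anticorrelated_line_gives_r_minus_one(self):
        events = [_event(f"i{k}", f"g{k}", d) for k, d in
                  enumerate([-0.3, -0.1, 0.1, 0.3, 0.2])]
        expression = self._expression(
            {f"g{k}": -d for k, d in enumerate([-0.3, -0.1, 0.1, 0.3, 0.2])}
        )
        result = integrate(events, expression)
        assert result.pearson_r_events == pytest.approx(-1.0)

    def test_quadrant_labels_follow_signs(self):
        events = [
            _event("i1", "g1", -0.2), _event("i2", "g2", -0.2),
            _event("i3", "g3", 0.2), _event("i4", "g4", 0.2),
            _event("i5", "g5", 0.0),
        ]
        expression = self._expression(
            {"g1": 1.0, "g2": -1.0, "g3": 1.0, "g4": -1.0, "g5": 1.0}
        )
        result = integrate(events, expression)
        quadrants = result.records.set_index("gene_id")["quadrant"]
        assert quadrants["g1"] == "IR_down_E_up"
        assert quadrants["g2"] == "IR_down_E_down"
        assert quadrants["g3"] == "IR_up_E_up"
        assert quadrants["g4"] == "IR_up_E_down"
        assert quadrants["g5"] == "unclassified"

    def test_quadrant_counts_conserve_gene_total(self):
        rng = np.random.default_rng(5)
        events = [
            _event(f"i{k}", f"g{k}", float(rng.normal(0, 0.2)))
            for k in range(60)
        ]
        expression = self._expression(
            {f"g{k}": float(rng.normal(0, 1)) for k in range(60)}
        )
        result = integrate(events, expression)
        assert result.records["quadrant"].value_counts().sum() == len(
            result.records
        )

    def test_panel_membership_labels(self):
        events = [_event("i1", "g1", -0.2), _event("i2", "g2", -0.2)]
        expression = self._expression({"g1": 1.0, "g2": 1.0})
        result = integrate(
            events, expression, panels={"pan": ["g1"], "A1": []}
        )
        labels = result.records.set_index("gene_id")["panel"]
        assert labels["g1"] == "pan" and labels["g2"] == "none"


class TestOverlapTest:
    def test_forced_overlap_is_null(self):
        assert overlap_test(10, 10, 10, 10).p_value == pytest.approx(1.0)

    def test_zero_overlap_upper_tail_near_one(self):
        assert overlap_test(0, 10, 10, 100).p_value > 0.6

    def test_matches_direct_hypergeometric_summation(self):
        """Upper-tail p equals the explicit sum of hypergeometric masses
        for every feasible instance on a grid with background <= 200."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(300):
            big_n = int(rng.integers(5, 201))
            n1 = int(rng.integers(1, big_n + 1))
            n2 = int(rng.integers(1, big_n + 1))
            lo = max(0, n1 + n2 - big_n)
            k = int(rng.integers(lo, min(n1, n2) + 1))
            expected = sum(
                math.comb(n1, j) * math.comb(big_n - n1, n2 - j) / math.comb(big_n, n2)
                for j in range(k, min(n1, n2) + 1)
            )
            result = overlap_test(k, n1, n2, big_n)
            assert result.p_value == pytest.approx(min(expected, 1.0), rel=1e-9)
            checked += 1
        assert checked == 300

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            overlap_test(11, 10, 20, 100)
        with pytest.raises(ValueError):
            overlap_test(0, 60, 60, 100)  # overlap below forced minimum


class TestThreewayOverlap:
    def test_observed_equal_expected_is_null(self):
        # expected = 200 * (50/200)^3 = 3.125
        stat, p, method = threeway_overlap_test([50, 50, 50], 3, 200)
        assert method == "chi-squared"
        assert p > 0.5

    def test_tenfold_excess_detected(self):
        # expected 5: N=1000, sets ~171 each -> observe 50
        sizes = [171, 171, 171]
        stat, p, method = threeway_overlap_test(sizes, 50, 1000)
        assert p < 0.01

    def test_small_expectation_uses_poisson_tail(self):
        sizes = [10, 10, 10]
        expected = 1000 * (10 / 1000) ** 3
        stat, p, method = threeway_overlap_test(sizes, 2, 1000)
        assert method == "poisson-exact"
        oracle = 1 - sum(
            math.exp(-expected) * expected**j / math.factorial(j) for j in (0, 1)
        )
        assert p == pytest.approx(oracle, rel=1e-9)


def reference_enrichment_score(scores, in_set):
    """Independent running-sum implementation used as the GSEA oracle."""
    n = len(scores)
    n_hits = sum(in_set)
    hit_total = sum(abs(s) for s, h in zip(scores, in_set) if h)
    running, best = 0.0, 0.0
    for s, h in zip(scores, in_set):
        if h:
            running += abs(s) / hit_total
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best = running
    return best


class TestGSEA:
    def _scores(self):
        return pd.Series(
            [3.0, 2.5, 2.0, 1.0, -0.5, -1.0, -2.0, -3.0],
            index=[f"g{k}" for k in range(8)],
        )

    def test_top_ranked_set_has_positive_es(self):
        result = gsea_preranked(self._scores(), {"g0", "g1", "g2"}, n_perm=200, seed=0)
        assert result.es > 0

    def test_exact_enumeration_matches_oracle(self):
        """With an 8-gene universe and 3-gene set the permutation null is
        enumerated; p must equal an independent exhaustive computation."""
        scores = self._scores()
        gene_set = {"g0", "g1", "g5"}
        result = gsea_preranked(scores, gene_set, n_perm=200, seed=1)
        assert result.exact and result.n_perm == 56

        values = scores.sort_values(ascending=False)
        in_set = [g in gene_set for g in values.index]
        es_obs = reference_enrichment_score(values.to_numpy(), in_set)
        assert result.es == pytest.approx(es_obs)

        perm = []
        for combo in itertools.combinations(range(8), 3):
            mask = [i in combo for i in range(8)]
            perm.append(reference_enrichment_score(values.to_numpy(), mask))
        same = [e for e in perm if np.sign(e) == np.sign(es_obs)]
        p_oracle = (1 + sum(abs(e) >= abs(es_obs) for e in same)) / (1 + len(same))
        assert result.p_value == pytest.approx(p_oracle)

    def test_seeded_runs_are_bit_reproducible(self):
        scores = pd.Series(
            np.random.default_rng(0).normal(size=40),
            index=[f"g{k}" for k in range(40)],
        )
        gene_set = {f"g{k}" for k in range(0, 12)}
        a = gsea_preranked(scores, gene_set, n_perm=300, seed=11)
        b = gsea_preranked(scores, gene_set, n_perm=300, seed=11)
        assert not a.exact
        assert (a.es, a.nes, a.p_value) == (b.es, b.nes, b.p_value)

    def test_reversed_ranking_negates_es_of_mirrored_set(self):
        scores = self._scores()
        mirrored = pd.Series(-scores.to_numpy()[::-1], index=scores.index[::-1])
        a = gsea_preranked(scores, {"g0", "g1"}, n_perm=200, seed=0)
        b = gsea_preranked(mirrored, {"g0", "g1"}, n_perm=200, seed=0)
        assert a.es == pytest.approx(-b.es)

    def test_es_bounded_by_one(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        order = np.argsort(-scores)
        for _ in range(50):
            mask = np.zeros(30, dtype=bool)
            mask[rng.choice(30, 5, replace=False)] = True
            es, _ = _enrichment_score(scores[order], mask[order])
            assert abs(es) <= 1.0 + 1e-12

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            gsea_preranked(self._scores(), {"absent"}, n_perm=200)


class TestSetEnrichment:
    def test_query_identical_set_ranks_first(self):
        background = {f"g{k}" for k in range(50)}
        query = {f"g{k}" for k in range(5)}
        collection = {
            "match": set(query),
            "random": {f"g{k}" for k in range(20, 40)},
        }
        result = set_enrichment(query, collection, background)
        assert result.loc[0, "set_name"] == "match"
        assert result.loc[0, "p_value"] < result.loc[1, "p_value"]

    def test_bh_adjustment_is_monotone_in_raw_p(self):
        rng = np.random.default_rng(3)
        background = {f"g{k}" for k in range(100)}
        query = set(rng.choice(sorted(background), 20, replace=False))
        collection = {
            f"s{j}": set(rng.choice(sorted(background), 15, replace=False))
            for j in range(12)
        }
        result = set_enrichment(query, collection, background)
        ordered = result.sort_values("p_value")
        assert ordered["p_adjusted"].is_monotonic_increasing
        assert (result["p_adjusted"] >= result["p_value"] - 1e-12).all()

    def test_empty_query_yields_empty_result(self):
        assert set_enrichment([], {"s": {"g1"}}, {"g1"}).empty


class TestGroupedLFC:
    def test_identical_groups_are_null(self):
        values = [0.1, 0.5, -0.2, 0.8, 0.0]
        _, p = grouped_lfc_comparison(values, values)
        assert p > 0.9

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 100)
        b = rng.normal(5, 1, 100)
        _, p = grouped_lfc_comparison(a, b)
        assert p < 1e-10

    def test_small_groups_match_exact_enumeration(self):
        a = [1.0, 4.0, 6.0, 9.0]
        b = [2.0, 3.0, 7.0, 11.0]
        stat, p = grouped_lfc_comparison(a, b)
        pooled = a + b
        observed_u = sum(1 for x in a for y in b if x > y)
        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(8) if i not in combo]
            u = sum(1 for x in ga for y in gb if x > y)
            if abs(u - 8.0) >= abs(observed_u - 8.0):
                count += 1
            total += 1
        assert p == pytest.approx(count / total)
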