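"""Sequence features, splice-site scoring, NMD rule, and group comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from retentio.annotation_io import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Transcript,
    derive_introns,
)
from retentio.intron_features import (
    ScoreTable,
    acceptor_window,
    compare_ir_sets,
    donor_window,
    gc_content,
    mean_conservation,
    predict_nmd,
    rbp_enrichment,
    reverse_complement,
    splice_site_score,
    train_splice_model,
)

from conftest import make_nmd_gene


class TestGC:
    @pytest.mark.parametrize(
        "seq, expected",
        [("ATGC", 0.5), ("GGCC", 1.0), ("ANGC", 2 / 3), ("atgc", 0.5)],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_is_undefined(self):
        assert math.isnan(gc_content("NNNN"))

    @given(st.text(alphabet="ACGTNacgtn", min_size=1, max_size=200))
    def test_bounds_and_case_invariance(self, seq):
        value = gc_content(seq)
        if not math.isnan(value):
            assert 0.0 <= value <= 1.0
        upper = gc_content(seq.upper())
        assert value == upper or (math.isnan(value) and math.isnan(upper))


class TestConservation:
    def _track(self, runs):
        track = CoverageTrack("cons")
        for start, end, value in runs:
            track.add_run("chr1", start, end, value)
        return track

    def test_constant_track(self):
        mean, reliable = mean_conservation(
            self._track([(0, 100, 0.8)]), GenomicInterval("chr1", 0, 100)
        )
        assert mean == pytest.approx(0.8) and reliable

    def test_mixed_values_average(self):
        track = self._track([(0, 50, 0.0), (50, 100, 1.0)])
        mean, _ = mean_conservation(track, GenomicInterval("chr1", 0, 100))
        assert mean == pytest.approx(0.5)

    def test_sparse_coverage_flagged_unreliable(self):
        mean, reliable = mean_conservation(
            self._track([(0, 20, 0.6)]), GenomicInterval("chr1", 0, 100)
        )
        assert mean == pytest.approx(0.6) and not reliable

    def test_no_coverage_undefined(self):
        mean, reliable = mean_conservation(
            self._track([(500, 600, 0.6)]), GenomicInterval("chr1", 0, 100)
        )
        assert math.isnan(mean) and not reliable


def _intron(chrom, start, end, gene="g1"):
    from retentio.annotation_io import Intron, intron_id_for

    iv = GenomicInterval(chrom, start, end)
    return Intron(
        intron_id_for(gene, iv), iv, gene,
        GenomicInterval(chrom, max(0, start - 50), start),
        GenomicInterval(chrom, end, end + 50),
        [iv],
    )


class TestRBPEnrichment:
    def _events(self, positions_by_chrom):
        rows = []
        for chrom, positions in positions_by_chrom.items():
            for pos in positions:
                rows.append(
                    {"chrom": chrom, "start": pos, "end": pos + 1,
                     "name": "RBP1", "score": 1, "strand": "+"}
                )
        return pd.DataFrame(rows)

    def test_equal_densities_give_unity(self):
        events = self._events({"c1": range(100, 110), "c2": range(100, 110)})
        table = rbp_enrichment(
            events, [_intron("c1", 100, 1100)], [_intron("c2", 100, 1100)]
        )
        assert table.loc[0, "enrichment"] == pytest.approx(1.0)

    def test_density_ratio_arithmetic(self):
        # 30 events over 10 kb retained vs 10 events over 10 kb other
        events = self._events({"c1": range(100, 130), "c2": range(100, 110)})
        table = rbp_enrichment(
            events, [_intron("c1", 100, 10_100)], [_intron("c2", 100, 10_100)]
        )
        assert table.loc[0, "enrichment"] == pytest.approx(3.0)

    def test_invariant_to_joint_scaling(self):
        base = self._events({"c1": range(100, 130), "c2": range(200, 210)})
        tripled = pd.concat(
            [base.assign(start=base["start"] + k, end=base["end"] + k)
             for k in (0, 1, 2)]
        )
        retained = [_intron("c1", 60, 5060)]
        other = [_intron("c2", 60, 5060)]
        a = rbp_enrichment(base, retained, other).loc[0, "enrichment"]
        b = rbp_enrichment(tripled, retained, other).loc[0, "enrichment"]
        assert a == pytest.approx(b)

    def test_zero_denominator_flagged(self):
        events = self._events({"c1": range(100, 110)})
        table = rbp_enrichment(
            events, [_intron("c1", 100, 1100)], [_intron("c2", 100, 1100)]
        )
        assert not table.loc[0, "defined"]
        assert math.isnan(table.loc[0, "enrichment"])


class TestSpliceSiteModel:
    def test_training_window_attains_maximum_over_all_windows(self):
        """A model trained on one repeated 9-mer scores that 9-mer at least
        as high as every other window (exhaustive enumeration)."""
        window = "CAGGTAAGT"  # canonical donor consensus
        model = train_splice_model([window] * 120, ["ACGT" * 200], "5ss")
        best = model.score(window)
        assert model.max_score_window() == window
        for other in itertools.product("ACGT", repeat=9):
            assert model.score("".join(other)) <= best + 1e-12

    def test_flat_foreground_scores_near_zero(self):
        windows = ["".join(w) for w in itertools.product("ACGT", repeat=1)] * 30
        windows = [(w * 9)[:9] for w in windows]
        model = train_splice_model(windows, ["ACGT" * 500], "5ss")
        # every base equally frequent at every position -> log-odds ~ 0
        assert abs(model.score("ACGTACGTA")) < 0.1

    def test_consensus_beats_random_windows(self):
        rng = np.random.default_rng(3)
        consensus = "CAGGTAAGT"
        train = []
        for _ in range(500):
            w = list(consensus)
            pos = rng.integers(0, 9)
            w[pos] = "ACGT"[rng.integers(0, 4)]
            train.append("".join(w))
        model = train_splice_model(train, ["ACGT" * 500], "5ss")
        random_scores = [
            model.score("".join(rng.choice(list("ACGT"), 9))) for _ in range(500)
        ]
        assert model.score(consensus) > np.percentile(random_scores, 95)

    def test_window_length_contract(self):
        with pytest.raises(ValueError):
            train_splice_model(["ACGTACGT"] * 120, ["ACGT"], "5ss")
        model = train_splice_model(["CAGGTAAGT"] * 120, ["ACGT"], "5ss")
        with pytest.raises(ValueError):
            splice_site_score("ACGT", model)

    def test_ambiguous_base_scored_with_background(self):
        model = train_splice_model(["CAGGTAAGT"] * 120, ["ACGT" * 100], "5ss")
        with_n = model.score("NAGGTAAGT")
        without_first = model.score("CAGGTAAGT") - (
            model.log2_fg[0, 1] - model.log2_bg[1]  # C at position 0
        )
        assert with_n == pytest.approx(without_first)

    def test_score_table_loader(self, tmp_path):
        path = tmp_path / "table.tsv"
        path.write_text("CAGGTAAGT\t8.5\nAAAAAAAAA\t-3.0\n")
        table = ScoreTable.read(path, "5ss")
        assert table.score("caggtaagt") == 8.5
        with pytest.raises(KeyError):
            table.score("CCCCCCCCC")


class TestWindowExtraction:
    def test_plus_strand_windows(self):
        chrom = "A" * 97 + "CAG" + "GTAAGT" + "T" * 68 + "TTTTTTTTTTTTTTTTTTAG" + "GCA" + "A" * 50
        # intron [100, 194): donor GTAAGT..., acceptor ...AG
        intron = _intron("c", 100, 194)
        seqs = {"c": chrom}
        assert donor_window(intron, seqs) == "CAGGTAAGT"
        assert acceptor_window(intron, seqs) == "TTTTTTTTTTTTTTTTTTAGGCA"

    def test_minus_strand_matches_mirrored_plus_case(self):
        plus_chrom = "A" * 97 + "CAG" + "GTAAGT" + "C" * 68 + "TTTTTTTTTTTTTTTTTTAG" + "GCA" + "A" * 50
        minus_chrom = reverse_complement(plus_chrom)
        length = len(plus_chrom)
        plus_intron = _intron("p", 100, 194)
        start, end = length - 194, length - 100
        from retentio.annotation_io import Intron, intron_id_for

        iv = GenomicInterval("m", start, end, "-")
        minus_intron = Intron(
            intron_id_for("g1", iv), iv, "g1",
            GenomicInterval("m", end, end + 3, "-"),
            GenomicInterval("m", start - 3, start, "-"),
            [iv],
        )
        seqs = {"p": plus_chrom, "m": minus_chrom}
        assert donor_window(minus_intron, seqs) == donor_window(plus_intron, seqs)
        assert acceptor_window(minus_intron, seqs) == acceptor_window(plus_intron, seqs)


class TestNMDRule:
    def test_internal_intron_ptc_far_upstream_triggers_nmd(self):
        tx, intron, seqs = make_nmd_gene(stop_at=90, retained="i1")
        call = predict_nmd(tx, intron, seqs, start_offset=0)
        assert call.nmd_predicted
        assert call.distance == 288 - 93  # well beyond the 50-nt rule

    def test_retained_final_intron_never_triggers(self):
        tx, intron, seqs = make_nmd_gene(stop_at=291, retained="i2")
        call = predict_nmd(tx, intron, seqs, start_offset=0)
        assert not call.nmd_predicted
        assert call.distance < 0  # stop lies downstream of the last junction

    def test_stop_just_upstream_of_junction_is_tolerated(self):
        # stop ends exactly 30 nt upstream of the last junction: within the
        # 50-nt window, so translation termination is considered normal
        tx, intron, seqs = make_nmd_gene(stop_at=255, retained="i1")
        call = predict_nmd(tx, intron, seqs, start_offset=0)
        assert not call.nmd_predicted
        assert call.distance == 30

    def test_longest_orf_fallback_finds_annotated_start(self):
        tx, intron, seqs = make_nmd_gene(stop_at=None, retained="i1")
        annotated = predict_nmd(tx, intron, seqs, start_offset=0)
        inferred = predict_nmd(tx, intron, seqs)
        assert annotated == inferred

    def test_no_orf_is_undefined(self):
        tx, intron, seqs = make_nmd_gene(stop_at=90, retained="i1")
        seqs = {"chrN": seqs["chrN"].replace("ATG", "ACC")}
        call = predict_nmd(tx, intron, seqs)
        assert not call.defined


class TestCompareIRSets:
    def _table(self, values):
        return pd.DataFrame({"length": values, "gc_fraction": values})

    def test_identical_groups_are_null(self):
        table = self._table([1.0, 2.0, 3.0, 4.0])
        result = compare_ir_sets(table, table, ["length", "gc_fraction"])
        assert (result["p_adjusted"] >= 0.9).all()

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(1)
        a = self._table(rng.normal(0, 1, 50))
        b = self._table(rng.normal(10, 1, 50))
        result = compare_ir_sets(a, b, ["length"])
        assert (result["p_adjusted"] < 0.001).all()

    def test_constant_feature_gives_p_one(self):
        a = self._table([5.0] * 6)
        result = compare_ir_sets(a, a, ["length"])
        assert (result["p_value"] == 1.0).all()

    def test_small_groups_match_exact_permutation(self):
        """For n=5 vs 5 without ties the rank-sum p equals the exhaustive
        permutation distribution of the U statistic."""
        a = [1.0, 3.0, 5.0, 7.0, 11.0]
        b = [2.0, 4.0, 9.0, 13.0, 15.0]
        result = compare_ir_sets(self._table(a), self._table(b), ["length"])

        pooled = a + b
        observed_u = sum(1 for x in a for y in b if x > y)
        count = 0
        total = 0
        for combo in itertools.combinations(range(10), 5):
            group_a = [pooled[i] for i in combo]
            group_b = [pooled[i] for i in range(10) if i not in combo]
            u = sum(1 for x in group_a for y in group_b if x > y)
            if abs(u - 12.5) >= abs(observed_u - 12.5):
                count += 1
            total += 1
        assert result.loc[0, "p_value"] == pytest.approx(count / total)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_ir_sets(self._table([1.0]), self._table([2.0] * 5), ["length"])
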