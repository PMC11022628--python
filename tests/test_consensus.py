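import numpy as np
import pandas as pd
import pytest

import methylprof as mp
from methylprof.calls import CALL_COLUMNS
from methylprof.consensus import (
    consensus_calls,
    consensus_site_frequency,
    normalize_llr,
    pair_reads,
    rule_consensus,
    train_consensus,
)


def calls_df(rows, source):
    return pd.DataFrame(
        [("chr1", pos, "+", rid, source, score, call) for pos, rid, score, call in rows],
        columns=CALL_COLUMNS,
    )


def pairs_df(scores):
    return pd.DataFrame(
        [("chr1", 10, "+", f"r{i}", a, b) for i, (a, b) in enumerate(scores)],
        columns=["sequence_id", "pos", "strand", "read_id",
                 "score_llr_normalized", "score_prob"],
    )


class TestNormalizeLLR:
    def test_logistic_midpoint(self):
        assert normalize_llr(0.0) == 0.5

    def test_saturates(self):
        assert normalize_llr(50.0) == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_value(self):
        assert normalize_llr(2.0) == pytest.approx(0.8807970779778823, abs=1e-15)

    def test_monotone(self, rng):
        x = np.sort(rng.normal(0, 5, size=100))
        y = normalize_llr(x)
        assert (np.diff(y) >= 0).all()
        assert ((y >= 0) & (y <= 1)).all()


class TestPairing:
    def test_inner_join_semantics(self):
        llr = calls_df([(10, "a", 3.0, "methylated"), (10, "b", 2.5, "methylated"),
                        (10, "c", -3.0, "unmethylated"), (10, "x1", 1.0, "ambiguous"),
                        (10, "x2", 1.0, "ambiguous")], "llr_caller")
        prob = calls_df([(10, "a", 0.9, "methylated"), (10, "b", 0.8, "methylated"),
                         (10, "c", 0.1, "unmethylated"), (10, "y1", 0.7, "methylated")],
                        "prob_caller")
        pairs, fallback = pair_reads(llr, prob)
        assert len(pairs) == 3
        assert len(fallback) == 3
        assert set(fallback["read_id"]) == {"x1", "x2", "y1"}
        a = pairs[pairs.read_id == "a"].iloc[0]
        assert a.score_llr_normalized == pytest.approx(normalize_llr(3.0))
        assert a.score_prob == 0.9

    def test_empty_prob_set_all_fallback(self):
        llr = calls_df([(10, "a", 3.0, "methylated")], "llr_caller")
        pairs, fallback = pair_reads(llr, llr.iloc[:0])
        assert len(pairs) == 0 and len(fallback) == 1

    def test_duplicates_keep_most_confident(self, caplog):
        llr = calls_df([(10, "a", 0.5, "ambiguous"), (10, "a", 4.0, "methylated")],
                       "llr_caller")
        prob = calls_df([(10, "a", 0.6, "methylated")], "prob_caller")
        with caplog.at_level("WARNING"):
            pairs, _ = pair_reads(llr, prob)
        assert len(pairs) == 1
        assert pairs.iloc[0].score_llr_normalized == pytest.approx(normalize_llr(4.0))
        assert "duplicate" in caplog.text

    def test_synthetic_join_matches_designed_overlap(self, tmp_path):
        cfg = mp.ScenarioConfig(n_chrom=1, chrom_length=60_000,
                                model=mp.MethylomeModel(coverage_lambda=8.0))
        synth = mp.generate_genome(3, cfg)
        truth = mp.plant_methylation(synth, cfg.model, seed=4)
        reads = mp.simulate_reads(synth, truth, cfg.model, seed=5, outdir=tmp_path,
                                  contexts=("CG",))
        llr = mp.parse_llr_records(reads.llr_path)
        prob = mp.parse_prob_records(reads.prob_path)
        pairs, _ = pair_reads(llr, prob)
        assert len(pairs) == reads.n_expected_pairs


class TestRuleConsensus:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(0.9, 0.8, "methylated"), (0.9, 0.2, "methylated"),
         (0.6, 0.4, "ambiguous"), (0.1, 0.3, "unmethylated")],
    )
    def test_mean_score_rule(self, a, b, expected):
        assert rule_consensus(pairs_df([(a, b)]))[0] == expected


class TestTrainedConsensus:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        pairs = pairs_df([(0.9, 0.9)] * 10 + [(0.1, 0.1)] * 10)
        pairs["label"] = [1] * 10 + [0] * 10
        model = train_consensus(pairs, seed=0)
        assert model.training_accuracy == 1.0
        assert model.n_trees == 3 and model.max_depth == 10

    def test_deterministic_under_seed(self, rng):
        pairs = pairs_df(list(zip(rng.uniform(size=300), rng.uniform(size=300))))
        pairs["label"] = (rng.uniform(size=300) < 0.5).astype(int)
        probe = pairs_df(list(zip(rng.uniform(size=100), rng.uniform(size=100))))
        m1 = train_consensus(pairs, seed=7)
        m2 = train_consensus(pairs, seed=7)
        assert np.array_equal(m1.predict(probe), m2.predict(probe))

    def test_single_class_training_rejected(self):
        pairs = pairs_df([(0.9, 0.9)] * 5)
        pairs["label"] = 1
        with pytest.raises(ValueError, match="single class"):
            train_consensus(pairs)

    def test_agreeing_reads_keep_their_call(self, rng):
        """When both callers agree confidently, consensus equals that call for
        the rule and for a model trained on agreement-dominated data."""
        n = 400
        labels = (rng.uniform(size=n) < 0.5).astype(int)
        a = np.where(labels, rng.uniform(0.7, 1.0, n), rng.uniform(0.0, 0.3, n))
        b = np.where(labels, rng.uniform(0.7, 1.0, n), rng.uniform(0.0, 0.3, n))
        pairs = pairs_df(list(zip(a, b)))
        pairs["label"] = labels
        expected = np.where(labels, "methylated", "unmethylated")
        assert np.array_equal(rule_consensus(pairs), expected)
        model = train_consensus(pairs, seed=1)
        assert np.array_equal(model.predict(pairs), expected)

    def test_beats_single_callers_under_asymmetric_noise(self, rng):
        """With independent asymmetric caller errors, held-out per-read
        consensus accuracy is at least each single caller's accuracy."""
        def draw(n):
            labels = (rng.uniform(size=n) < 0.5).astype(int)
            # class-conditional score distributions with different separations
            # and an upward bias for the first caller (asymmetric errors)
            a = rng.normal(np.where(labels, 0.66, 0.42), 0.18)
            b = rng.normal(np.where(labels, 0.60, 0.40), 0.12)
            pairs = pairs_df(list(zip(np.clip(a, 0, 1), np.clip(b, 0, 1))))
            pairs["label"] = labels
            return pairs
        train, test = draw(4000), draw(2000)
        model = train_consensus(train, seed=2)
        pred = model.predict(test) == "methylated"
        acc_consensus = (pred == test["label"].to_numpy().astype(bool)).mean()
        acc_a = ((test["score_llr_normalized"] > 0.5) == test["label"]).mean()
        acc_b = ((test["score_prob"] > 0.5) == test["label"]).mean()
        assert acc_consensus >= max(acc_a, acc_b)


class TestConsensusFrequency:
    @pytest.fixture
    def tiny_index(self):
        # plus-strand CG sites at 10 and 20
        return mp.build_context_index({"chr1": "A" * 10 + "CG" + "A" * 8 + "CG" + "A" * 10})

    def test_aggregation(self, tiny_index):
        pairs = pairs_df([(0.9, 0.9)] * 5 + [(0.1, 0.1)] * 5)
        pairs["pos"] = 10
        cons = consensus_calls(pairs)
        freq = consensus_site_frequency(cons, cons.iloc[:0], tiny_index)
        assert freq.iloc[0].frequency == 0.5
        assert freq.iloc[0].n_total == 10

    def test_fallback_policy_accounting(self, tiny_index):
        pairs = pairs_df([(0.9, 0.9)] * 6)
        pairs["pos"] = 10
        cons = consensus_calls(pairs)
        fallback = calls_df([(20, f"f{i}", 0.9, "methylated") for i in range(6)],
                            "prob_caller")
        with_fb = consensus_site_frequency(cons, fallback, tiny_index,
                                           min_coverage=5, fallback_policy="single")
        without = consensus_site_frequency(cons, fallback, tiny_index,
                                           min_coverage=5, fallback_policy="drop")
        assert len(with_fb) - len(without) == 1  # the fallback-only site
        with pytest.raises(ValueError):
            consensus_site_frequency(cons, fallback, tiny_index, fallback_policy="x")

    def test_zero_noise_consensus_equals_single_tool(self, tmp_path):
        cfg = mp.ScenarioConfig(
            n_chrom=1, chrom_length=40_000,
            model=mp.MethylomeModel(coverage_lambda=10.0,
                                    noise=mp.CallerNoise.noiseless()),
        )
        synth = mp.generate_genome(9, cfg)
        truth = mp.plant_methylation(synth, cfg.model, seed=10)
        reads = mp.simulate_reads(synth, truth, cfg.model, seed=11,
                                  outdir=tmp_path, contexts=("CG",))
        idx = mp.build_context_index(synth.genome)
        llr = mp.parse_llr_records(reads.llr_path)
        prob = mp.parse_prob_records(reads.prob_path)
        pairs, fallback = pair_reads(llr, prob)
        freq_cons = consensus_site_frequency(consensus_calls(pairs), fallback, idx)
        freq_single = mp.aggregate_site_frequency(prob, idx)
        merged = freq_cons.merge(freq_single, on=["sequence_id", "pos", "strand"])
        assert np.allclose(merged["frequency_x"], merged["frequency_y"])
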