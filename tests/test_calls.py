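import numpy as np
import pandas as pd
import pytest

import methylprof as mp
from methylprof.calls import (
    LLR_FILE_COLUMNS,
    PROB_FILE_COLUMNS,
    aggregate_prob_file,
    aggregate_site_frequency,
    combine_strands,
    global_levels,
    parse_llr_records,
    parse_prob_records,
    split_by_context,
)
from methylprof.io import FormatError


def write_llr(path, rows):
    lines = ["\t".join(LLR_FILE_COLUMNS)]
    for r in rows:
        lines.append("\t".join(str(x) for x in r))
    path.write_text("\n".join(lines) + "\n")


def write_prob(path, rows):
    lines = ["\t".join(PROB_FILE_COLUMNS)]
    for r in rows:
        lines.append("\t".join(str(x) for x in r))
    path.write_text("\n".join(lines) + "\n")


def llr_row(chrom="chr1", strand="+", start=100, end=100, read="r1", llr=3.1,
            n_motifs=1, seq="AAACGAAA"):
    return (chrom, strand, start, end, read, llr, llr / 2, -llr / 2, 1, n_motifs, seq)


class TestParseLLR:
    def test_threshold_rule(self, tmp_path):
        p = tmp_path / "l.tsv"
        write_llr(p, [llr_row(llr=3.1), llr_row(read="r2", llr=-0.5),
                      llr_row(read="r3", llr=-2.0)])
        calls = parse_llr_records(p, llr_threshold=2.0)
        assert list(calls["call"]) == ["methylated", "ambiguous", "unmethylated"]
        assert list(calls["pos"]) == [100, 100, 100]

    def test_motif_group_split_positions(self, tmp_path):
        p = tmp_path / "l.tsv"
        write_llr(p, [llr_row(start=1000, end=1005, llr=2.5, n_motifs=2,
                              seq="AACGTTACGTA")])
        calls = parse_llr_records(p)
        # CG offsets 2 and 7 -> positions 1000 and 1000 + (7 - 2)
        assert sorted(calls["pos"]) == [1000, 1005]
        assert set(calls["call"]) == {"methylated"}
        assert set(calls["read_id"]) == {"r1"}

    def test_too_few_motifs_in_sequence_errors_with_line(self, tmp_path):
        p = tmp_path / "l.tsv"
        write_llr(p, [llr_row(n_motifs=3, seq="AACGTTACGTA")])
        with pytest.raises(FormatError, match="line 2"):
            parse_llr_records(p)

    def test_group_splitting_conserves_reads(self, tmp_path, rng):
        rows, total_motifs = [], 0
        for i in range(50):
            n = int(rng.integers(1, 4))
            seq = "TT" + "CGAT" * n + "TT"
            rows.append(llr_row(read=f"r{i}", start=10 * i, n_motifs=n, seq=seq,
                                llr=float(rng.normal())))
            total_motifs += n
        p = tmp_path / "l.tsv"
        write_llr(p, rows)
        assert len(parse_llr_records(p)) == total_motifs

    def test_raising_threshold_never_adds_unambiguous_calls(self, tmp_path, rng):
        p = tmp_path / "l.tsv"
        write_llr(p, [llr_row(read=f"r{i}", llr=float(rng.normal(0, 3)))
                      for i in range(200)])
        counts = [
            (parse_llr_records(p, llr_threshold=t)["call"] != "ambiguous").sum()
            for t in (0.5, 1.0, 2.0, 4.0)
        ]
        assert counts == sorted(counts, reverse=True)


def prob_row(chrom="chr1", pos=100, strand="+", read="r1", pu=0.1, pm=0.9, label=1):
    return (chrom, pos, strand, pos, read, "t", pu, pm, label, "AAAACAAAA")


class TestParseProb:
    def test_call_rules(self, tmp_path):
        p = tmp_path / "p.tsv"
        write_prob(p, [prob_row(pm=0.91, pu=0.09),
                       prob_row(read="r2", pm=0.5, pu=0.5),
                       prob_row(read="r3", pm=0.2, pu=0.8)])
        calls = parse_prob_records(p)
        assert list(calls["call"]) == ["methylated", "ambiguous", "unmethylated"]
        assert calls["raw_score"].tolist() == [0.91, 0.5, 0.2]

    def test_probabilities_must_be_valid(self, tmp_path):
        p = tmp_path / "p.tsv"
        write_prob(p, [prob_row(pm=1.2, pu=-0.2)])
        with pytest.raises(FormatError, match="outside"):
            parse_prob_records(p)
        write_prob(p, [prob_row(pm=0.6, pu=0.6)])
        with pytest.raises(FormatError, match="summing"):
            parse_prob_records(p)

    def test_sites_filter(self, tmp_path):
        p = tmp_path / "p.tsv"
        write_prob(p, [prob_row(pos=100), prob_row(pos=200, read="r2")])
        sites = pd.DataFrame(
            {"sequence_id": ["chr1"], "pos": [200], "strand": ["+"]}
        )
        calls = parse_prob_records(p, sites=sites)
        assert list(calls["pos"]) == [200]


def make_calls(n_m, n_u, n_a, pos=50, context_call="prob"):
    rows = []
    for i, (count, call) in enumerate(
        [(n_m, "methylated"), (n_u, "unmethylated"), (n_a, "ambiguous")]
    ):
        for k in range(count):
            rows.append(("chr1", pos, "+", f"r{i}_{k}", "prob_caller", 0.9, call))
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "pos", "strand", "read_id", "source", "raw_score", "call"],
    )


@pytest.fixture
def tiny_index():
    return mp.build_context_index({"chr1": "A" * 50 + "CGA" + "A" * 47})
    # CG site at +50 / -51


class TestAggregate:
    def test_simple_frequency(self, tiny_index):
        freq = aggregate_site_frequency(make_calls(7, 3, 0), tiny_index)
        assert len(freq) == 1
        row = freq.iloc[0]
        assert (row.n_total, row.n_methylated, row.frequency) == (10, 7, 0.7)
        assert (row.context, row.subcontext) == ("CG", "CG")

    def test_ambiguous_excluded_before_counting(self, tiny_index):
        freq = aggregate_site_frequency(make_calls(4, 4, 2), tiny_index)
        assert freq.iloc[0].n_total == 8
        assert freq.iloc[0].frequency == 0.5

    def test_min_coverage_suppression(self, tiny_index):
        assert len(aggregate_site_frequency(make_calls(2, 1, 0), tiny_index,
                                            min_coverage=5)) == 0

    def test_reference_mismatch_dropped(self, tiny_index, caplog):
        calls = make_calls(7, 0, 0, pos=10)  # not a cytosine
        with caplog.at_level("WARNING"):
            freq = aggregate_site_frequency(calls, tiny_index)
        assert len(freq) == 0
        assert "mismatch" in caplog.text

    def test_frequency_rationality(self, small_freq):
        f = small_freq
        assert np.array_equal(
            (f["frequency"] * f["n_total"]).round().astype(int), f["n_methylated"]
        )
        assert f["frequency"].between(0, 1).all()

    def test_streamed_aggregation_equals_in_memory(self, tmp_path, tiny_index, rng):
        rows = [prob_row(pos=50, read=f"r{i}",
                         pm=round(float(rng.uniform()), 3),
                         pu=round(1 - round(float(rng.uniform()), 3), 3))
                for i in range(40)]
        # rebuild pu consistently
        rows = [(c, p, s, ps, r, t, round(1 - pm, 3), pm, lab, k)
                for (c, p, s, ps, r, t, pu, pm, lab, k) in rows]
        f = tmp_path / "p.tsv"
        write_prob(f, rows)
        a = aggregate_prob_file(f, tiny_index, min_coverage=1, chunksize=7)
        b = aggregate_site_frequency(parse_prob_records(f), tiny_index, min_coverage=1)
        pd.testing.assert_frame_equal(a, b)


class TestSplitAndLevels:
    def test_split_partitions_rows(self, toy_freq_factory):
        rows = []
        for i, ctx in enumerate(["CG", "CHG", "CHH"] * 3):
            rows.append(("chr1", i, "+", ctx, ctx if ctx == "CG" else ctx[:2] + "A", 10, 5))
        freq = toy_freq_factory(rows)
        parts = split_by_context(freq)
        assert {k: len(v) for k, v in parts.items()} == {"CG": 3, "CHG": 3, "CHH": 3}
        assert sum(len(v) for v in parts.values()) == len(freq)
        empty = split_by_context(freq.iloc[:0])
        assert all(len(v) == 0 for v in empty.values())

    def test_global_levels_mean(self, toy_freq_factory):
        freq = toy_freq_factory([
            ("chr1", 1, "+", "CG", "CG", 10, 2),
            ("chr1", 5, "+", "CG", "CG", 10, 4),
        ])
        lv = global_levels(freq)
        assert lv.iloc[0].mean_frequency == pytest.approx(0.3)
        assert lv.iloc[0].n_sites == 2
        # absent context is missing, not zero
        assert "CHH" not in set(lv["context"])

    def test_all_methylated(self, toy_freq_factory):
        freq = toy_freq_factory([("chr1", 1, "+", "CG", "CG", 5, 5)])
        assert global_levels(freq).iloc[0].mean_frequency == 1.0


class TestCombineStrands:
    def test_cg_partners_summed_at_plus_coordinate(self, toy_freq_factory):
        freq = toy_freq_factory([
            ("chr1", 10, "+", "CG", "CG", 10, 7),
            ("chr1", 11, "-", "CG", "CG", 6, 3),
        ])
        merged = combine_strands(freq)
        assert len(merged) == 1
        row = merged.iloc[0]
        assert (row.pos, row.strand) == (10, ".")
        assert (row.n_total, row.n_methylated) == (16, 10)
        assert row.frequency == pytest.approx(10 / 16)

    def test_chg_partner_offset_is_two(self, toy_freq_factory):
        freq = toy_freq_factory([
            ("chr1", 10, "+", "CHG", "CAG", 10, 5),
            ("chr1", 12, "-", "CHG", "CTG", 10, 1),
        ])
        merged = combine_strands(freq)
        assert len(merged) == 1
        assert merged.iloc[0].n_total == 20
        assert merged.iloc[0].subcontext == "CAG"  # plus-strand subcontext kept

    def test_chh_passes_through_and_reads_conserved(self, toy_freq_factory):
        freq = toy_freq_factory([
            ("chr1", 10, "+", "CG", "CG", 10, 7),
            ("chr1", 11, "-", "CG", "CG", 6, 3),
            ("chr1", 30, "+", "CHH", "CTA", 8, 2),
        ])
        merged = combine_strands(freq)
        assert merged["n_total"].sum() == freq["n_total"].sum()
        chh = merged[merged.context == "CHH"]
        assert list(chh["strand"]) == ["+"]

    def test_unpartnered_site_kept(self, toy_freq_factory):
        freq = toy_freq_factory([("chr1", 10, "+", "CG", "CG", 10, 7)])
        merged = combine_strands(freq)
        assert len(merged) == 1 and merged.iloc[0].n_total == 10
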