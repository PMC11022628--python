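import numpy as np
import pandas as pd
import pytest

import methylprof as mp
from methylprof.features import (
    divergence_landscape,
    gene_set_profiles,
    metagene_profile,
    region_breakdown,
    repeat_coverage_summary,
    te_metaprofile,
)
from methylprof.io import GeneModel

import oracles


def uniform_freq(index, value=0.5):
    """Constant-frequency table over every classified site of an index."""
    df = index[index["context"] != "UNCLASSIFIED"].copy()
    df["n_total"] = 10
    df["n_methylated"] = int(value * 10)
    df["frequency"] = value
    return df


def mirror_dataset(synth, freq):
    """Reverse-complement every chromosome and remap genes and frequencies."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    genome = {}
    lengths = {}
    for sid, seq in synth.genome.items():
        genome[sid] = "".join(comp[b] for b in reversed(seq.residues))
        lengths[sid] = seq.length
    genes = []
    for g in synth.genes:
        L = lengths[g.sequence_id]
        genes.append(
            GeneModel(
                gene_id=g.gene_id,
                sequence_id=g.sequence_id,
                strand="-" if g.strand == "+" else "+",
                start=L - g.end,
                end=L - g.start,
                exons=sorted((L - e, L - s) for s, e in g.exons),
                cds=sorted((L - e, L - s) for s, e in g.cds),
            )
        )
    f = freq.copy()
    L = f["sequence_id"].astype(str).map(lengths)
    f["pos"] = L - 1 - f["pos"]
    f["strand"] = np.where(f["strand"].astype(str) == "+", "-", "+")
    return genome, genes, f


class TestMetagene:
    def test_flat_methylome_gives_flat_curve(self, small_synth):
        synth, _ = small_synth
        index = mp.build_context_index(synth.genome)
        prof = metagene_profile(uniform_freq(index), synth.genes)
        populated = prof.table.dropna(subset=["mean_frequency"])
        assert len(populated) > 0
        assert np.allclose(populated["mean_frequency"], 0.5)

    def test_bin_axis_shape(self, small_synth, small_freq):
        synth, _ = small_synth
        prof = metagene_profile(small_freq, synth.genes, flank_bp=2000,
                                flank_bins=10, body_bins=20)
        assert set(prof.table["bin"]) == set(range(40))
        seg = prof.table[prof.table["context"] == "CG"].set_index("bin")["segment"]
        assert (seg.loc[:9] == "upstream").all()
        assert (seg.loc[10:29] == "body").all()
        assert (seg.loc[30:] == "downstream").all()

    def test_mirror_symmetry(self, small_synth, small_freq):
        """Reverse-complementing the genome and flipping strands leaves the
        metagene curve unchanged."""
        synth, _ = small_synth
        prof = metagene_profile(small_freq, synth.genes)
        _, genes_m, freq_m = mirror_dataset(synth, small_freq)
        prof_m = metagene_profile(freq_m, genes_m)
        pd.testing.assert_frame_equal(prof.table, prof_m.table)

    def test_short_gene_fractional_positions(self, toy_freq_factory):
        gene = GeneModel("g", "c", "+", 100, 110, exons=[(100, 110)])
        freq = toy_freq_factory([("c", 100 + i, "+", "CG", "CG", 10, 10)
                                 for i in range(10)])
        prof = metagene_profile(freq, [gene], flank_bp=100, flank_bins=5, body_bins=20)
        body = prof.table[(prof.table.segment == "body") & (prof.table.context == "CG")]
        assert body["n_sites"].sum() == 10  # no error, all sites assigned


class TestRegionBreakdown:
    def make_gene(self, strand="+"):
        # exons [1000,1200) [1500,1700) [2000,2200)
        exons = [(1000, 1200), (1500, 1700), (2000, 2200)]
        return GeneModel("g", "c", strand, 1000, 2200, exons=exons, cds=list(exons))

    def test_intron_definitions(self):
        g = self.make_gene("-")
        assert len(g.introns) == 2
        assert g.first_intron == (1700, 2000)  # highest gap on minus strand

    def test_decile_binning(self, toy_freq_factory):
        freq = toy_freq_factory([("c", 1100, "+", "CG", "CG", 10, 9)])
        rb = region_breakdown(freq, [self.make_gene()])
        hist = rb.histogram
        row = hist[(hist.region == "CDS") & (hist.context == "CG") & (hist.freq_bin == 9)]
        assert row["n_sites"].iloc[0] == 1
        assert hist[(hist.region == "CDS") & (hist.context == "CG")]["n_sites"].sum() == 1

    def test_frequency_one_in_last_bin(self, toy_freq_factory):
        freq = toy_freq_factory([("c", 1100, "+", "CG", "CG", 10, 10)])
        rb = region_breakdown(freq, [self.make_gene()])
        hist = rb.histogram
        assert hist[(hist.region == "CDS") & (hist.freq_bin == 9)]["n_sites"].sum() == 1

    def test_genes_without_cds_skipped_and_counted(self, toy_freq_factory):
        g = GeneModel("g2", "c", "+", 100, 300, exons=[(100, 300)], cds=[])
        rb = region_breakdown(
            toy_freq_factory([("c", 150, "+", "CG", "CG", 10, 5)]), [g]
        )
        assert rb.n_genes == 0 and rb.n_genes_skipped == 1
        assert rb.histogram["n_sites"].sum() == 0

    def test_region_assignment_never_loses_sites(self, toy_freq_factory):
        g = self.make_gene()
        positions = [500, 1100, 1300, 1600, 1850, 2100, 2500]  # one per region + flanks
        freq = toy_freq_factory([("c", p, "+", "CG", "CG", 10, 5) for p in positions])
        rb = region_breakdown(freq, [g])
        by_region = rb.means.groupby("region")["n_sites"].sum()
        assert by_region["upstream_1kb"] == 1      # 500 in [0, 1000)
        assert by_region["CDS"] == 3               # 1100, 1600, 2100
        assert by_region["first_intron"] == 1      # 1300 in [1200, 1500)
        assert by_region["other_introns"] == 1     # 1850 in [1700, 2000)
        assert by_region["downstream_1kb"] == 1    # 2500 in [2200, 3200)


class TestGeneSets:
    def test_full_set_equals_baseline(self, small_synth, small_freq):
        synth, _ = small_synth
        ids = [g.gene_id for g in synth.genes]
        out = gene_set_profiles(small_freq, synth.genes, {"all_again": ids})
        pd.testing.assert_frame_equal(
            out["baseline"]["metagene"].table, out["all_again"]["metagene"].table
        )
        assert out["unresolved"]["all_again"] == []

    def test_unknown_ids_reported_exactly(self, small_synth, small_freq):
        synth, _ = small_synth
        ids = [synth.genes[0].gene_id, "nope1", "nope2", "nope3"]
        out = gene_set_profiles(small_freq, synth.genes, {"s": ids})
        assert out["unresolved"]["s"] == ["nope1", "nope2", "nope3"]
        assert out["s"]["n_genes"] == 1

    def test_empty_set_skipped(self, small_synth, small_freq, caplog):
        synth, _ = small_synth
        with caplog.at_level("WARNING"):
            out = gene_set_profiles(small_freq, synth.genes, {"ghost": ["zzz"]})
        assert "ghost" not in out


class TestTEProfiles:
    def test_superfamily_grouping_merges_families(self, small_synth, small_freq):
        synth, _ = small_synth
        by_superfam = te_metaprofile(small_freq, synth.repeats, group_by="superfamily")
        by_name = te_metaprofile(small_freq, synth.repeats, group_by="repeat_name")
        copia_names = set(
            synth.repeats[synth.repeats.superfamily == "Copia"]["repeat_name"]
        )
        assert len(copia_names) > 1
        assert by_superfam["Copia"].n_elements == sum(
            by_name[n].n_elements for n in copia_names
        )

    def test_absent_group_not_in_output(self, small_synth, small_freq):
        synth, _ = small_synth
        profs = te_metaprofile(small_freq, synth.repeats, group_by="superfamily")
        assert set(profs) == set(synth.repeats["superfamily"].unique())

    def test_low_confidence_flag(self, small_synth, small_freq):
        synth, _ = small_synth
        profs = te_metaprofile(small_freq, synth.repeats, group_by="repeat_name",
                               min_elements=10_000)
        assert all(p.table.attrs["low_confidence"] for p in profs.values())

    def test_invalid_grouping_rejected(self, small_synth, small_freq):
        synth, _ = small_synth
        with pytest.raises(ValueError):
            te_metaprofile(small_freq, synth.repeats, group_by="species")


def repeats_df(rows):
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "start", "end", "strand", "repeat_name",
                 "repeat_class", "superfamily", "divergence_pct"],
    )


class TestRepeatCoverage:
    def test_disjoint_sum(self):
        reps = repeats_df([("c", 0, 100, "+", "f", "LTR", "Copia", 1.0),
                           ("c", 200, 250, "+", "f", "LTR", "Copia", 1.0)])
        cov = repeat_coverage_summary(reps, {"c": "A" * 1000})
        cls = cov[(cov.level == "class") & (cov.group == "LTR")].iloc[0]
        assert cls.percent == pytest.approx(15.0)

    def test_nested_elements_merged(self):
        reps = repeats_df([("c", 0, 100, "+", "f", "LTR", "Copia", 1.0),
                           ("c", 20, 70, "+", "f", "LTR", "Copia", 1.0)])
        cov = repeat_coverage_summary(reps, {"c": "A" * 1000})
        assert cov[(cov.level == "class")].iloc[0].percent == pytest.approx(10.0)

    def test_matches_bitmask_oracle(self, small_synth):
        synth, _ = small_synth
        cov = repeat_coverage_summary(synth.repeats, synth.genome)
        length = sum(s.length for s in synth.genome.values())
        for cls, part in synth.repeats.groupby("repeat_class"):
            expected = sum(
                oracles.masked_bp_bruteforce(
                    list(zip(p["start"], p["end"])), synth.genome[str(sid)].length
                )
                for sid, p in part.groupby("sequence_id")
            )
            got = cov[(cov.level == "class") & (cov.group == cls)].iloc[0]
            assert got.bp == expected
            assert got.percent == pytest.approx(100.0 * expected / length)


class TestDivergenceLandscape:
    def test_binning(self):
        reps = repeats_df([("c", 0, 120, "+", "f", "LTR", "Copia", 1.2),
                           ("c", 200, 280, "+", "f", "LTR", "Copia", 1.8)])
        land = divergence_landscape(reps)
        fam = land[(land.level == "family") & (land.group == "f")]
        assert fam[fam.bin_left == 1.0]["bp"].iloc[0] == 200

    def test_conservation(self, small_synth):
        synth, _ = small_synth
        land = divergence_landscape(synth.repeats)
        totals = (synth.repeats["end"] - synth.repeats["start"]).groupby(
            synth.repeats["repeat_name"]
        ).sum()
        fam = land[land.level == "family"].groupby("group")["bp"].sum()
        assert fam.to_dict() == totals.to_dict()

    def test_overflow_bin_warned(self, caplog):
        reps = repeats_df([("c", 0, 100, "+", "f", "LTR", "Copia", 63.0)])
        with caplog.at_level("WARNING"):
            land = divergence_landscape(reps)
        fam = land[land.level == "family"]
        assert fam["bin_left"].iloc[0] == 50.0
        assert "overflow" in caplog.text
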