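"""Codon extraction, incomplete stops, translation, RSCU, amino-acid usage."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.codon_usage import (CODON_TO_AA, CodonCountTable, InternalStopError,
                                  POOLED_FAMILIES, SPLIT_FAMILIES, aa_usage,
                                  coding_record_from_sequence,
                                  expected_sense_codons, extract_coding_record,
                                  rscu, translate)

SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")


class TestCodingRecord:
    def test_toy_cds_with_complete_stop(self):
        r = coding_record_from_sequence("toy", "ATGAAATAA")
        assert r.codons == ["ATG", "AAA"]
        assert r.stop_codon == "TAA"
        assert r.aa_length == 2

    @pytest.mark.parametrize("size, stop_len", [
        (691, 1),    # COII-style: trailing T
        (1046, 2),   # ND2-style: trailing TA
        (975, 3),    # ND1-style: complete stop
    ])
    def test_incomplete_stop_resolution_by_length(self, size, stop_len):
        body = "ATG" + "GCA" * ((size - stop_len) // 3 - 1)
        tail = {1: "T", 2: "TA", 3: "TAA"}[stop_len]
        r = coding_record_from_sequence("toy", body + tail)
        assert len(r.stop_codon) == stop_len
        assert r.aa_length == (size - stop_len) // 3

    def test_internal_stop_raises_with_position(self):
        with pytest.raises(InternalStopError, match="codon 2"):
            coding_record_from_sequence("toy", "ATGAGATTTTAA")  # AGA = mito stop

    def test_sense_codon_bookkeeping_matches_published_sizes(self, ref_df):
        """3*(sense codons) + stop length == feature size for all 13 PCGs
        in each of the three species columns."""
        pcgs = ref_df[ref_df["category"] == "PCG"]
        for sp in ("st", "sa", "sm"):
            for _, row in pcgs.iterrows():
                size = int(row[f"{sp}_end"]) - int(row[f"{sp}_start"]) + 1
                stop = row[f"{sp}_term"]
                assert 3 * int(row["aa"]) + len(stop) == size, row["name"]
                assert expected_sense_codons(size, len(stop) == 3) == int(row["aa"])

    def test_synthetic_pcgs_reproduce_start_stop_conventions(self, root_genome):
        genome, _ = root_genome
        records = {f.name: extract_coding_record(genome, f)
                   for f in genome.table.pcgs}
        assert records["COI"].start_codon == "GTG"
        others = {n: r.start_codon for n, r in records.items() if n != "COI"}
        assert set(others.values()) == {"ATG"}
        incomplete = {n for n, r in records.items() if len(r.stop_codon) < 3}
        assert incomplete == {"ND2", "COII", "ATP6", "COIII", "ND3", "ND4", "CYTB"}

    def test_synthetic_pcgs_translate_cleanly(self, root_genome):
        genome, _ = root_genome
        for f in genome.table.pcgs:
            r = extract_coding_record(genome, f)
            protein = translate(r.codons)
            assert "*" not in protein
            assert protein.startswith("M")


class TestTranslate:
    def test_vertebrate_mito_idiosyncrasies(self):
        assert translate(["TGA"], initiation=False) == "W"   # Trp, not stop
        assert translate(["ATA"], initiation=False) == "M"
        assert translate(["AGA"], initiation=False) == "*"
        assert translate(["GTG", "TGA"]) == "MW"             # GTG initiator
        assert translate(["GTG"], initiation=False) == "V"

    def test_ambiguous_codon(self):
        assert translate(["ANG"], initiation=False) == "X"


class TestRscu:
    def test_equal_usage_gives_unity(self):
        table = CodonCountTable()
        table.counts.update({c: 5 for c in SPLIT_FAMILIES["A"]})
        vals = rscu(table)
        for c in SPLIT_FAMILIES["A"]:
            assert vals[c][1] == pytest.approx(1.0)

    def test_pooled_leucine_hand_example(self):
        # 6-codon Leu family {TTA:6, TTG:0, CTT:2, CTC:0, CTA:4, CTG:0}:
        # RSCU(TTA) = 6 * 6/12 = 3.0
        table = CodonCountTable()
        table.counts.update({"TTA": 6, "CTT": 2, "CTA": 4})
        vals = rscu(table, split_leu_ser=False)
        assert vals["TTA"][1] == pytest.approx(3.0)
        # split convention: TTA's family is the 2-codon Leu(UUR): 2 * 6/6 = 2.0
        assert rscu(table)["TTA"][1] == pytest.approx(2.0)

    def test_zero_family_flagged_undefined(self):
        vals = rscu(CodonCountTable())
        fam, val, undefined = vals["TGC"]
        assert val == 0.0 and undefined

    @settings(deadline=None, max_examples=40)
    @given(st.dictionaries(st.sampled_from(SENSE_CODONS),
                           st.integers(min_value=0, max_value=50)))
    def test_family_rscu_sums_to_family_size(self, counts):
        table = CodonCountTable()
        table.counts.update(counts)
        vals = rscu(table)
        for fam, codons in SPLIT_FAMILIES.items():
            total = sum(table.counts.get(c, 0) for c in codons)
            if total > 0:
                assert sum(vals[c][1] for c in codons) == pytest.approx(len(codons))


class TestAaUsage:
    def test_toy_counts(self):
        table = CodonCountTable()
        table.counts.update({"ATG": 1, "AAA": 2})
        usage = aa_usage(table)
        assert usage["M"] == 1 and usage["K"] == 2

    def test_leu_ser_split_and_pooled(self):
        table = CodonCountTable()
        table.counts.update({"TTA": 3, "CTA": 4, "TCA": 2, "AGC": 5})
        usage = aa_usage(table)
        assert (usage["L1"], usage["L2"], usage["L"]) == (3, 4, 7)
        assert (usage["S1"], usage["S2"], usage["S"]) == (2, 5, 7)

    def test_total_sense_codons_per_synthetic_genome(self, root_genome):
        """The default gene-length profile implies exactly 3800 sense codons."""
        genome, _ = root_genome
        table = CodonCountTable.from_genome(genome)
        assert table.total_codons == 3800
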