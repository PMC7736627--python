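"""p-distances and Nei-Gojobori Ka/Ks, checked against exhaustive oracles."""

from fractions import Fraction
from itertools import permutations

import numpy as np
import pytest

from Bio.Seq import Seq

from mitocomp.divergence import (classify_selection, codon_partition_distances,
                                 codon_sites, jukes_cantor, nei_gojobori,
                                 p_distance, pathway_differences)

STOPS = {"TAA", "TAG", "AGA", "AGG"}


def mito_aa(codon: str) -> str:
    """Independent translation route (Biopython) for the oracle."""
    return str(Seq(codon).translate(table=2))


def oracle_sites(codon: str):
    """Brute-force normalized NG86 site counts via Biopython translation."""
    s = Fraction(0)
    for pos in range(3):
        syn = valid = 0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if mut in STOPS:
                continue
            valid += 1
            syn += mito_aa(mut) == mito_aa(codon)
        s += Fraction(syn, valid)
    return s, 3 - s


def oracle_pathways(c1: str, c2: str):
    """Exhaustive minimal-pathway enumeration, stop-transit paths excluded."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in permutations(diff):
        cur, syn, nsyn, dead = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS:
                dead = True
                break
            syn += mito_aa(cur) == mito_aa(nxt)
            nsyn += mito_aa(cur) != mito_aa(nxt)
            cur = nxt
        if not dead:
            results.append((syn, nsyn))
    if not results:
        return None
    k = len(results)
    return (Fraction(sum(r[0] for r in results), k),
            Fraction(sum(r[1] for r in results), k))


def random_codon_seq(rng, n_codons):
    out = []
    while len(out) < n_codons:
        codon = "".join(rng.choice(list("ACGT"), 3))
        if codon not in STOPS:
            out.append(codon)
    return "".join(out)


class TestPDistance:
    def test_examples(self):
        assert p_distance("ACGT", "ACGT")[0] == 0.0
        assert p_distance("AAAA", "TTTT")[0] == 1.0
        p, n = p_distance("AAAAAAAATT", "AAAAAAAAAA")
        assert (p, n) == (0.2, 10)

    def test_pairwise_deletion(self):
        p, n = p_distance("ANAT", "AAAA")
        assert n == 3 and p == pytest.approx(1 / 3)

    def test_zero_comparable_sites(self):
        with pytest.raises(ValueError, match="zero comparable"):
            p_distance("NNN", "ACG")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            p_distance("ACGT", "ACG")


class TestCodonPartition:
    def test_third_position_only_divergence(self):
        a = "ATGGCTCGA".replace("CGA", "CGT")  # keep frame
        a, b = "ATGGCTCGT", "ATAGCACGG"  # diffs only at 3rd positions
        r = codon_partition_distances("toy", ("x", "y"), a, b)
        assert r.p12 == 0.0 and r.p3 == pytest.approx(1.0)
        assert (r.sites12, r.sites3) == (6, 3)

    def test_frame_violation(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            codon_partition_distances("toy", ("x", "y"), "ACGTA", "ACGTA")


class TestSiteCounting:
    def test_fourfold_and_nondegenerate(self):
        s, n = codon_sites("GGA")  # Gly: 3rd position fully synonymous
        assert s >= 1 and s + n == 3
        # Met is two-fold (ATA/ATG) in the mito code: 1 of 3 third-position
        # changes is synonymous
        assert codon_sites("ATG")[0] == Fraction(1, 3)

    def test_sites_match_oracle_for_all_sense_codons(self):
        for codon in sorted(set("".join(p) for p in permutations("ACGT" * 3, 3))):
            if codon in STOPS:
                continue
            assert codon_sites(codon) == oracle_sites(codon), codon

    def test_site_conservation_is_exact(self):
        rng = np.random.default_rng(7)
        seq = random_codon_seq(rng, 100)
        total = Fraction(0)
        for i in range(0, len(seq), 3):
            s, n = codon_sites(seq[i:i + 3])
            total += s + n
        assert total == 300


class TestPathways:
    def test_single_difference(self):
        sd, nd, flag = pathway_differences("GGA", "GGG")  # Gly->Gly
        assert (sd, nd, flag) == (1, 0, False)
        sd, nd, _ = pathway_differences("GGA", "GCA")  # Gly->Ala
        assert (sd, nd) == (0, 1)

    def test_two_difference_codon_matches_enumeration(self):
        sd, nd, _ = pathway_differences("TTT", "GTA")
        assert (sd, nd) == oracle_pathways("TTT", "GTA")

    def test_exhaustive_oracle_on_seeded_codon_pairs(self):
        """Pathway averaging equals exhaustive enumeration on all pairs from a
        seeded sample of short codon sequences."""
        rng = np.random.default_rng(42)
        sample = [random_codon_seq(rng, k) for k in (1, 2, 3, 5) for _ in range(8)]
        checked = 0
        for a in sample:
            for b in sample:
                if len(a) != len(b):
                    continue
                exp_sd, exp_nd = Fraction(0), Fraction(0)
                skip = False
                for i in range(0, len(a), 3):
                    got = oracle_pathways(a[i:i + 3], b[i:i + 3])
                    if got is None:  # all pathways stop-blocked: fallback case
                        skip = True
                        break
                    exp_sd, exp_nd = exp_sd + got[0], exp_nd + got[1]
                if skip:
                    continue
                res = nei_gojobori(a, b)
                assert res.Sd == pytest.approx(float(exp_sd))
                assert res.Nd == pytest.approx(float(exp_nd))
                checked += 1
        assert checked >= 250

    def test_sd_nd_sum_to_differences(self):
        rng = np.random.default_rng(3)
        a, b = random_codon_seq(rng, 50), random_codon_seq(rng, 50)
        res = nei_gojobori(a, b)
        ndiff = sum(x != y for x, y in zip(a, b))
        assert res.Sd + res.Nd == pytest.approx(ndiff)


class TestNeiGojobori:
    def test_identical_sequences(self):
        res = nei_gojobori("ATGGCT", "ATGGCT")
        assert res.Ka == 0 and res.Ks == 0 and res.ratio is None
        assert "Ks == 0" in " ".join(res.flags)

    def test_fourfold_third_position_difference(self):
        res = nei_gojobori("ATGGGA", "ATGGGC")
        assert res.Nd == 0 and res.Ka == 0 and res.Sd == 1

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        a, b = random_codon_seq(rng, 30), random_codon_seq(rng, 30)
        r1, r2 = nei_gojobori(a, b), nei_gojobori(b, a)
        assert (r1.S, r1.N, r1.Sd, r1.Nd) == (r2.S, r2.N, r2.Sd, r2.Nd)

    def test_site_sum_identity(self):
        rng = np.random.default_rng(5)
        a = random_codon_seq(rng, 200)
        res = nei_gojobori(a, a)
        assert res.S + res.N == pytest.approx(600)

    def test_jc_correction_monotone(self):
        for p in np.linspace(0.01, 0.74, 40):
            assert jukes_cantor(p) >= p
        with pytest.raises(ValueError):
            jukes_cantor(0.75)


class TestClassification:
    @pytest.mark.parametrize("ratio, expected", [
        (0.135, "purifying"), (0.188, "purifying"),
        (1.0, "neutral"), (2.3, "positive"),
    ])
    def test_classes(self, ratio, expected):
        res = nei_gojobori("ATGGCT", "ATGGCT")
        res.ratio = ratio
        assert classify_selection(res) == expected

    def test_undefined_propagates(self):
        res = nei_gojobori("ATGGCT", "ATGGCT")
        assert res.selection_class == "undefined"
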