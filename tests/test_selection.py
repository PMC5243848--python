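import itertools
import math

import numpy as np
import pytest

from taxotyper.selection import (branch_group_dnds, nei_gojobori,
                                 potential_synonymous_sites,
                                 segregating_sites_and_pi, tajimas_d)

from conftest import make_msa, random_msa


def random_coding_msa(rng, nseq, ncodons, nmut=4):
    """Stop-free coding alignment: a random base sequence with a few
    substitutions per sequence (substitutions avoid creating stops)."""
    from taxotyper.selection import _codon_map

    table = _codon_map()
    codons = [c for c in table if table[c] != "*"]
    base = [codons[int(rng.integers(len(codons)))] for _ in range(ncodons)]
    seqs = []
    for _ in range(nseq):
        cods = list(base)
        muts = 0
        while muts < nmut:
            ci = int(rng.integers(ncodons))
            pos = int(rng.integers(3))
            b = "ACGT"[int(rng.integers(4))]
            cand = cods[ci][:pos] + b + cods[ci][pos + 1:]
            if table[cand] == "*" or cand == cods[ci]:
                continue
            cods[ci] = cand
            muts += 1
        seqs.append("".join(cods))
    return make_msa(seqs)


def brute_force_tajima(seqs):
    """Independent recomputation of D from first principles."""
    n = len(seqs)
    cols = list(zip(*seqs))
    cols = [c for c in cols if all(x in "ACGT" for x in c)]
    S = sum(len(set(c)) > 1 for c in cols)
    diffs = [sum(a != b for a, b in zip(seqs[i], seqs[j]))
             for i, j in itertools.combinations(range(n), 2)]
    # recount differences on the retained columns only
    diffs = [
        sum(c[i] != c[j] for c in cols)
        for i, j in itertools.combinations(range(n), 2)
    ]
    pi = float(np.mean(diffs))
    if S == 0:
        return S, pi, None
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    D = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return S, pi, D


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        msa = make_msa(["ACGT"] * 4)
        st = tajimas_d(msa)
        assert st.S == 0
        assert math.isnan(st.tajimas_d)

    def test_singleton_case_hand_worked(self):
        """n=4, one singleton segregating site: pi=0.5, S=1, D ~ -0.61."""
        msa = make_msa(["AAAA", "AAAA", "AAAA", "AAAC"])
        st = tajimas_d(msa)
        assert st.S == 1
        assert st.pi == pytest.approx(0.5)
        assert st.tajimas_d == pytest.approx(-0.61, abs=0.005)

    def test_sign_flips_for_intermediate_frequency(self):
        """Same n and S; a 2/2 site yields positive D, a singleton negative."""
        singleton = tajimas_d(make_msa(["AAAA", "AAAA", "AAAA", "AAAC"]))
        balanced = tajimas_d(make_msa(["AAAA", "AAAA", "AAAC", "AAAC"]))
        assert singleton.tajimas_d < 0 < balanced.tajimas_d

    def test_matches_brute_force_on_random_alignments(self, rng):
        for _ in range(50):
            msa = random_msa(rng, 5, 60, alphabet="AACGT")
            st = tajimas_d(msa)
            S, pi, D = brute_force_tajima([r.residues for r in msa])
            assert st.S == S
            assert st.pi == pytest.approx(pi, abs=1e-9)
            if D is None:
                assert math.isnan(st.tajimas_d)
            else:
                assert st.tajimas_d == pytest.approx(D, abs=1e-9)

    def test_matches_dendropy_oracle(self, rng):
        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import popgenstat

        for _ in range(5):
            msa = random_msa(rng, 6, 80, alphabet="AAACGT")
            st = tajimas_d(msa)
            if st.S == 0:
                continue
            data = "\n".join(f">{r.id}\n{r.residues}" for r in msa)
            mat = dendropy.DnaCharacterMatrix.get(data=data, schema="fasta")
            assert st.tajimas_d == pytest.approx(
                popgenstat.tajimas_d(mat), abs=1e-9)

    def test_gap_columns_removed_alignment_wide(self):
        # the gap column must be dropped for every sequence (complete deletion)
        msa = make_msa(["A-AAA", "ACAAA", "ACAAA", "ACAAC"])
        S, pi = segregating_sites_and_pi(msa)
        assert S == 1  # only the final column counts

    def test_pi_two_ways_agree(self, rng):
        """Pairwise counting equals the site-frequency formula."""
        for _ in range(20):
            msa = random_msa(rng, 6, 40, alphabet="AACGT")
            S, pi = segregating_sites_and_pi(msa)
            n = 6
            arr = msa.to_array()
            total = 0.0
            for col in arr.T:
                for b in set(col):
                    x = (col == b).mean()
                    total += x * (1 - x) * n / (n - 1)
            assert pi == pytest.approx(total, abs=1e-9)


class TestNeiGojobori:
    def test_synonymous_pair(self):
        # one synonymous Phe difference, padded with identical Lys codons
        msa = make_msa(["TTT" + "AAA" * 5, "TTC" + "AAA" * 5])
        st = nei_gojobori(msa)
        assert st.dn == pytest.approx(0.0)
        assert st.ds > 0
        assert st.dn_ds == pytest.approx(0.0)

    def test_identical_pair_undefined_ratio(self):
        st = nei_gojobori(make_msa(["TTTAAA", "TTTAAA"]))
        assert math.isnan(st.dn_ds)

    @pytest.mark.parametrize("codon, expected", [
        ("TTT", 1 / 3),   # only position-3 T->C is synonymous
        ("CTG", 4 / 3),   # Leu: 4-fold at pos 3 plus T->C at pos 1 (CTG->TTG)
        ("ATG", 0.0),     # Met: no synonymous neighbor
        ("GGG", 1.0),     # Gly: 4-fold third position
    ])
    def test_potential_synonymous_sites(self, codon, expected):
        assert potential_synonymous_sites(codon) == pytest.approx(expected)

    def test_potential_sites_match_enumeration_oracle(self, rng):
        from taxotyper.selection import _codon_map

        table = _codon_map()
        codons = [c for c in table if table[c] != "*"]
        for codon in rng.choice(codons, 20, replace=False):
            syn = 0
            for pos in range(3):
                for b in "ACGT":
                    if b == codon[pos]:
                        continue
                    mut = codon[:pos] + b + codon[pos + 1:]
                    if table[mut] == table[codon]:
                        syn += 1
            assert potential_synonymous_sites(codon) == pytest.approx(syn / 3)

    def test_nonsynonymous_pair_positive_ratio(self):
        # one nonsynonymous (Phe->Val) and one synonymous (Phe) difference
        msa = make_msa(["TTTTTC" + "AAA" * 6, "GTTTTT" + "AAA" * 6])
        st = nei_gojobori(msa)
        assert st.dn > 0 and st.ds > 0

    def test_length_not_multiple_of_three_errors(self):
        with pytest.raises(ValueError):
            nei_gojobori(make_msa(["TTTT", "TTTC"]))

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            nei_gojobori(make_msa(["TAATTT", "TTTTTT"]))

    def test_matches_codon_path_oracle_single_differences(self, rng):
        """For pairs differing by single-nucleotide codon changes, Sd and Nd
        are directly countable; check dN/dS classification pair by pair."""
        from taxotyper.selection import _codon_map, _pathway_counts

        table = _codon_map()
        codons = [c for c in table if table[c] != "*"]
        for _ in range(100):
            c1 = codons[int(rng.integers(len(codons)))]
            pos = int(rng.integers(3))
            for b in "ACGT":
                c2 = c1[:pos] + b + c1[pos + 1:]
                if c2 == c1 or table[c2] == "*":
                    continue
                sd, nd = _pathway_counts(c1, c2)
                if table[c1] == table[c2]:
                    assert (sd, nd) == (1.0, 0.0)
                else:
                    assert (sd, nd) == (0.0, 1.0)

    def test_two_difference_pathway_averaging(self):
        """TTT -> CTC: paths via CTT (nonsyn, then syn) and TTC (syn, then
        nonsyn); both allowed, so Sd = Nd = 1."""
        from taxotyper.selection import _pathway_counts

        sd, nd = _pathway_counts("TTT", "CTC")
        assert sd == pytest.approx(1.0)
        assert nd == pytest.approx(1.0)


class TestBranchGroupDnds:
    def test_single_group_matches_pooled(self, rng):
        msa = random_coding_msa(rng, 4, 12)
        pooled = nei_gojobori(msa, "loc")
        grouped = branch_group_dnds({"loc": msa},
                                    {r.id: "g" for r in msa})
        got = grouped["loc"]["g"]
        assert got.dn == pytest.approx(pooled.dn, nan_ok=True)
        assert got.ds == pytest.approx(pooled.ds, nan_ok=True)

    def test_groups_are_independent(self, rng):
        msa = random_coding_msa(rng, 6, 12)
        grouping = {r.id: ("g1" if i < 3 else "g2")
                    for i, r in enumerate(msa)}
        both = branch_group_dnds({"loc": msa}, grouping)
        only_g1 = branch_group_dnds(
            {"loc": make_msa([r.residues for r in msa.records[:3]],
                             ids=[r.id for r in msa.records[:3]])},
            {r.id: "g1" for r in msa.records[:3]})
        assert both["loc"]["g1"].dn == pytest.approx(
            only_g1["loc"]["g1"].dn, nan_ok=True)

    def test_singleton_group_skipped_with_warning(self, rng):
        msa = random_coding_msa(rng, 3, 12)
        grouping = {msa[0].id: "g1", msa[1].id: "g1", msa[2].id: "solo"}
        with pytest.warns(UserWarning, match="solo"):
            out = branch_group_dnds({"loc": msa}, grouping)
        assert "solo" not in out["loc"]
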