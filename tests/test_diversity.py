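"""Diversity statistics, including the NG86 exhaustive pathway oracle."""

from itertools import permutations

import numpy as np
import pytest

from urfkit.alignment import LocusAlignment
from urfkit.codes import ALL_CODONS
from urfkit.diversity import (
    calculate_pi,
    classify_sites,
    jukes_cantor,
    ng86_pairwise,
    ng86_tables,
    pinpis,
)


# ---------------------------------------------------------------------------
# independent oracle: literal enumeration of every mutational pathway
# ---------------------------------------------------------------------------

def oracle_ng86(seq_a, seq_b, code, stop_policy="exclude"):
    aa = code.codon_to_aa
    stops = code.stop_codons

    def codon_sites(c):
        s = n = 0.0
        for pos in range(3):
            for base in "ACGT":
                if base == c[pos]:
                    continue
                nb = c[:pos] + base + c[pos + 1:]
                if nb in stops:
                    if stop_policy == "nonsynonymous":
                        n += 1
                elif aa[nb] == aa[c]:
                    s += 1
                else:
                    n += 1
        return s / 3, n / 3

    sd = nd = S = N = 0.0
    for k in range(0, len(seq_a), 3):
        c1, c2 = seq_a[k:k + 3], seq_b[k:k + 3]
        if set(c1 + c2) - set("ACGT") or c1 in stops or c2 in stops:
            continue
        diff = [p for p in range(3) if c1[p] != c2[p]]
        paths = []
        for order in permutations(diff):
            cur, s_, n_, ok = c1, 0.0, 0.0, True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if nxt in stops and stop_policy == "exclude":
                    ok = False
                    break
                same = (nxt not in stops and cur not in stops
                        and aa[nxt] == aa[cur])
                s_, n_ = s_ + same, n_ + (not same)
                cur = nxt
            if ok:
                paths.append((s_, n_))
        if not paths and diff:
            continue  # all pathways blocked: codon pair skipped
        if paths:
            sd += float(np.mean([p[0] for p in paths]))
            nd += float(np.mean([p[1] for p in paths]))
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
    return jukes_cantor(nd / N), jukes_cantor(sd / S), N, S


def _random_codon_pairs(code, rng, n_codons=30, n_changes=8, allow_stops=True):
    sense = list(code.sense_codons)
    a = "".join(rng.choice(sense, n_codons))
    b = list(a)
    for _ in range(n_changes):
        for _attempt in range(20):
            i = int(rng.integers(0, 3 * n_codons))
            new = rng.choice([x for x in "ACGT" if x != b[i]])
            cand = b.copy()
            cand[i] = new
            codon = "".join(cand[3 * (i // 3):3 * (i // 3) + 3])
            if allow_stops or codon not in code.stop_codons:
                b = cand
                break
    return a, "".join(b)


class TestNg86:
    def test_identical_sequences_zero(self, code4):
        dn, ds, n, s = ng86_pairwise("AAATTTGGG", "AAATTTGGG", code4)
        assert dn == 0.0 and ds == 0.0 and n + s == pytest.approx(9, abs=1.5)

    def test_single_synonymous_change(self, code4):
        # Lys AAA -> AAG in a longer context so the JC correction is defined
        a = "GCTGCTGCTGCTAAA"
        b = "GCTGCTGCTGCTAAG"
        dn, ds, n, s = ng86_pairwise(a, b, code4)
        assert dn == 0.0 and ds > 0.0

    def test_symmetry(self, code4, rng):
        for _ in range(10):
            a, b = _random_codon_pairs(code4, rng)
            assert ng86_pairwise(a, b, code4) == ng86_pairwise(b, a, code4)

    def test_sites_sum_to_three_away_from_stops(self, code4):
        tab = ng86_tables(code4, "exclude")
        stop_adjacent = set()
        for c in code4.stop_codons:
            for pos in range(3):
                for base in "ACGT":
                    stop_adjacent.add(c[:pos] + base + c[pos + 1:])
        for i, codon in enumerate(ALL_CODONS):
            if codon in code4.stop_codons:
                continue
            total = tab.site_s[i] + tab.site_n[i]
            if codon in stop_adjacent:
                assert total < 3.0
            else:
                assert total == pytest.approx(3.0)

    def test_matches_pathway_oracle_on_random_pairs(self, code4, rng):
        for _ in range(40):
            a, b = _random_codon_pairs(code4, rng)
            dn, ds, n, s = ng86_pairwise(a, b, code4)
            dn_o, ds_o, n_o, s_o = oracle_ng86(a, b, code4)
            assert (n, s) == pytest.approx((n_o, s_o))
            assert (dn, ds) == pytest.approx((dn_o, ds_o), nan_ok=True)

    def test_matches_biopython_reference_convention(self, code4, rng):
        from Bio import Align
        from Bio.Align import analysis
        from Bio.Data import CodonTable

        tbl = CodonTable.unambiguous_dna_by_id[4]
        for _ in range(25):
            a, b = _random_codon_pairs(code4, rng, n_changes=5, allow_stops=False)
            dn_bp, ds_bp = analysis.calculate_dn_ds(
                Align.Alignment([a, b]), method="NG86", codon_table=tbl)
            dn, ds, _, _ = ng86_pairwise(a, b, code4, stop_policy="nonsynonymous")
            assert (dn, ds) == pytest.approx((dn_bp, ds_bp), abs=1e-10)

    def test_ambiguous_codons_skipped_in_both(self, code4):
        a, b = "GCTGCTGCTAAATTT", "GCTGCTGCTAAGTTT"
        dn1, ds1, n1, s1 = ng86_pairwise(a, b, code4)
        dn2, ds2, n2, s2 = ng86_pairwise(a + "NNN", b + "GGG", code4)
        assert (dn1, ds1, n1, s1) == (dn2, ds2, n2, s2)


class TestCalculatePi:
    def test_identical_rows_zero(self):
        aln = {"a": "ACGT" * 25, "b": "ACGT" * 25}
        assert calculate_pi(aln) == 0.0

    def test_two_sequence_closed_form(self):
        a = "A" * 100
        b = "A" * 99 + "T"
        assert calculate_pi({"a": a, "b": b}) == pytest.approx(0.01)

    def test_equals_mean_pairwise_hamming(self, rng):
        rows = {f"i{k}": "".join(rng.choice(list("ACGT"), 80)) for k in range(4)}
        mats = {k: np.frombuffer(v.encode(), dtype=np.uint8) for k, v in rows.items()}
        keys = list(rows)
        ds = [np.mean(mats[keys[i]] != mats[keys[j]])
              for i in range(4) for j in range(i + 1, 4)]
        assert calculate_pi(rows) == pytest.approx(float(np.mean(ds)))

    def test_row_permutation_invariance(self, rng):
        rows = {f"i{k}": "".join(rng.choice(list("ACGT"), 50)) for k in range(3)}
        assert calculate_pi(rows) == pytest.approx(
            calculate_pi(dict(reversed(list(rows.items())))))

    def test_sample_size_correction_flag(self):
        rows = {"a": "A" * 10, "b": "T" + "A" * 9}
        assert calculate_pi(rows, sample_size_correction=True) == pytest.approx(0.2)

    def test_fewer_than_two_rows_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            calculate_pi({"a": "ACGT"})


class TestPinpis:
    def test_pure_synonymous_alignment_ratio_zero(self, code4):
        rows = {"i1": "GCTAAACCT" * 5, "i2": "GCTAAGCCT" * 5, "i3": "GCTAAACCT" * 5}
        r = pinpis(LocusAlignment("syn", rows, status="coding"), code4)
        assert r.piN == 0.0 and r.piS > 0.0 and r.ratio == 0.0

    def test_pure_nonsynonymous_alignment_ratio_na(self, code4):
        rows = {"i1": "GCTAAACCT" * 5, "i2": "GCTGAACCT" * 5, "i3": "GCTAAACCT" * 5}
        r = pinpis(LocusAlignment("non", rows, status="coding"), code4)
        assert r.piN > 0.0 and r.piS == 0.0 and np.isnan(r.ratio)

    def test_ratio_of_means_not_mean_of_ratios(self, code4, rng):
        # with 3 rows piN/piS must equal mean(dN)/mean(dS) over the 3 pairs
        sense = list(code4.sense_codons)
        base = "".join(rng.choice(sense, 60))
        rows = {}
        for k in range(3):
            b = list(base)
            for _ in range(6):
                i = int(rng.integers(len(b)))
                b[i] = rng.choice([x for x in "ACGT" if x != b[i]])
            rows[f"i{k}"] = "".join(b)
        r = pinpis(LocusAlignment("x", rows, status="coding"), code4)
        pairs = [ng86_pairwise(rows["i0"], rows["i1"], code4),
                 ng86_pairwise(rows["i0"], rows["i2"], code4),
                 ng86_pairwise(rows["i1"], rows["i2"], code4)]
        piN = np.nanmean([p[0] for p in pairs])
        piS = np.nanmean([p[1] for p in pairs])
        assert r.piN == pytest.approx(piN) and r.piS == pytest.approx(piS)
        assert r.ratio == pytest.approx(piN / piS)


class TestClassifySites:
    def test_invariant_alignment_all_invariant(self, code4):
        aln = LocusAlignment("x", {"a": "ATGAAA", "b": "ATGAAA"}, status="coding")
        assert all(s.klass == "invariant" for s in classify_sites(aln, code4))

    def test_single_synonymous_snp(self, code4):
        aln = LocusAlignment(
            "x", {"a": "AAATTT", "b": "AAGTTT", "c": "AAATTT"}, status="coding")
        sites = classify_sites(aln, code4)
        assert [s.klass for s in sites] == ["synonymous", "invariant"]
        assert sites[0].minority_individuals == ("b",)

    def test_consistent_with_pinpis_numerators(self, code4, beroe_like):
        for loc in [l for l in beroe_like.loci if l.status == "coding"][:5]:
            r = pinpis(loc, code4)
            classes = {s.klass for s in classify_sites(loc, code4)}
            assert (r.piN > 0) == bool(classes & {"nonsynonymous", "both"})
            assert (r.piS > 0) == bool(classes & {"synonymous", "both"})
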