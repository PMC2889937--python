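"""Feature catalogue: pairing, bulges, position, composition, compactness."""
import math

import numpy as np
import pytest

from mirspot.energy import DuplexStructure
from mirspot.features import (
    CATALOGUE,
    DEFAULT_MODEL_FEATURES,
    NUCLEOTIDE_CODE,
    bulge_features,
    compactness,
    compositional_features,
    extract_features,
    pairing_features,
    positional_features,
)
from mirspot.sequences import RnaSequence
from mirspot.synthetic import random_duplex_structure
from mirspot.zones import CandidateZone

from conftest import random_rna


def perfect_structure(mi, params):
    win = mi.reverse_complement()
    m = len(mi)
    return DuplexStructure.from_pairs(
        [(i, m + 1 - i) for i in range(1, m + 1)], mi, win, params), win


def zone_for(structure, utr, anchor=None):
    return CandidateZone(
        utr_id=utr.id, mirna_id="mi", start=structure.target_footprint[0],
        end=structure.target_footprint[1], representative=structure,
        representative_anchor=anchor or structure.anchor,
    )


class TestPairingFeatures:
    def test_perfect_22mer(self, params, rng):
        mi = random_rna(rng, 22, "mi")
        s, _ = perfect_structure(mi, params)
        f = pairing_features(s, mi)
        assert f["seed8_pairings"] == 8
        assert f["pairings_3prime_8"] == 8
        assert f["longest_stretch"] == 22
        assert f["binding_asymmetry"] == 1.0
        assert f["total_pairings"] == 22
        assert f["consecutive_3prime_2gap"] == 22
        assert f["gu_total"] == 0

    def test_seed_only_structure(self, params):
        mi = RnaSequence("mi", "GCGCGCGCAAAAAAAAAAAAAA")
        win = RnaSequence("w", "AAGCGCGCG")  # pairs microRNA 2..8
        pairs = [(i, 11 - i) for i in range(2, 9)]
        s = DuplexStructure.from_pairs(pairs, mi, win, params)
        f = pairing_features(s, mi)
        assert f["seed8_pairings"] == 7
        assert f["pairings_3prime_8"] == 0
        # 5' side has 7 paired bases, 3' side none: pseudocount ratio (0+1)/1
        assert f["binding_asymmetry"] == 0.0

    def test_counts_match_naive_recount(self, params, rng):
        """Counting features equal an independent per-definition recount."""
        for _ in range(200):
            mi = random_rna(rng, int(rng.integers(10, 23)), "mi")
            s, win = random_duplex_structure(mi, rng, params)
            f = pairing_features(s, mi)
            m = len(mi)
            mi_set = {i for i, _ in s.pairs}
            assert f["seed8_pairings"] == len([i for i in mi_set if i <= 8])
            assert f["pairings_3prime_8"] == len([i for i in mi_set if i > m - 8])
            assert f["total_pairings"] == len(s.pairs)
            # longest stretch by scanning all starting pairs
            best = 0
            for a in range(len(s.pairs)):
                k = a
                while (k + 1 < len(s.pairs)
                       and s.pairs[k + 1][0] == s.pairs[k][0] + 1
                       and s.pairs[k + 1][1] == s.pairs[k][1] - 1):
                    k += 1
                best = max(best, k - a + 1)
            assert f["longest_stretch"] == best
            # 3'-end run with a 2-gap budget, recounted forward
            top = max(mi_set)
            count, gaps, q = 0, 0, top
            while q >= 1:
                if q in mi_set:
                    count += 1
                else:
                    gaps += 1
                    if gaps > 2:
                        break
                q -= 1
            assert f["consecutive_3prime_2gap"] == count


class TestBulgeFeatures:
    def test_perfect_duplex_has_no_bulges(self, params, rng):
        mi = random_rna(rng, 22, "mi")
        s, _ = perfect_structure(mi, params)
        f = bulge_features(s)
        assert all(v == 0 for v in f.values())

    def test_single_mirna_bulge_of_three(self, params):
        mi = RnaSequence("mi", "GCGCAAAGCGC")
        win = RnaSequence("w", "GCGCGCGC")
        pairs = [(i, 9 - i) for i in range(1, 5)]
        pairs += [(i, 12 - i) for i in range(8, 12)]
        s = DuplexStructure.from_pairs(pairs, mi, win, params)
        f = bulge_features(s)
        assert f["mi_bulge_count"] == 1
        assert f["mi_bulges_len3"] == 1
        assert f["mi_bulge_total_len"] == 3
        assert f["t_bulge_count"] == 0
        assert f["symmetric_bulges"] == 0

    def test_matches_gap_scanning_oracle(self, params, rng):
        for _ in range(200):
            mi = random_rna(rng, int(rng.integers(12, 23)), "mi")
            s, _ = random_duplex_structure(mi, rng, params)
            f = bulge_features(s)
            mi_pos = sorted(i for i, _ in s.pairs)
            t_pos = sorted(j for _, j in s.pairs)
            mi_gaps = [b - a - 1 for a, b in zip(mi_pos, mi_pos[1:]) if b - a > 1]
            t_gaps = [b - a - 1 for a, b in zip(t_pos, t_pos[1:]) if b - a > 1]
            assert f["mi_bulge_count"] == len(mi_gaps)
            assert f["t_bulge_count"] == len(t_gaps)
            assert f["mi_bulge_total_len"] == sum(mi_gaps)
            assert f["t_bulge_total_len"] == sum(t_gaps)
            for ell in range(1, 6):
                assert f[f"mi_bulges_len{ell}"] == mi_gaps.count(ell)
            for ell in range(1, 7):
                assert f[f"t_bulges_len{ell}"] == t_gaps.count(ell)
            assert f["t_bulges_len7plus"] == sum(g >= 7 for g in t_gaps)
            assert f["t_bulge_mean_len"] == pytest.approx(
                np.mean(t_gaps) if t_gaps else 0.0)


class TestPositionalFeatures:
    def _zone_at(self, params, rng, utr_len, anchor):
        mi = random_rna(rng, 10, "mi")
        site = mi.reverse_complement().residues
        pad_left = anchor - len(site)
        seq = ("G" * pad_left + site + "G" * (utr_len - anchor))[:utr_len]
        utr = RnaSequence("ut", seq)
        m = len(mi)
        pairs = [(i, anchor + 1 - i) for i in range(1, m + 1)]
        s = DuplexStructure.from_pairs(pairs, mi, utr, params)
        return zone_for(s, utr), utr, mi

    def test_bin_boundaries(self, params, rng):
        zone, utr, mi = self._zone_at(params, rng, 100, 12)
        zone.representative_anchor = 1
        assert positional_features(zone, utr, mi)["utr_position_bin"] == 1
        zone.representative_anchor = 100
        assert positional_features(zone, utr, mi)["utr_position_bin"] == 100

    def test_bin_closed_form(self, params, rng):
        zone, utr, mi = self._zone_at(params, rng, 1210, 473)
        assert positional_features(zone, utr, mi)["utr_position_bin"] == 40

    def test_anchor_nucleotides_read_through_register(self, params, rng):
        zone, utr, mi = self._zone_at(params, rng, 80, 40)
        f = positional_features(zone, utr, mi)
        # fully paired: t1 opposite position 1 at the anchor, t9 eight back
        assert f["t1_anchor"] == NUCLEOTIDE_CODE[utr[39]]
        assert f["t9_anchor"] == NUCLEOTIDE_CODE[utr[31]]
        assert f["t1_sw_anchor"] == (1.0 if utr[39] in "AU" else 0.0)


class TestCompositionalFeatures:
    def _fixed_zone(self, params, site, up, down):
        mi = RnaSequence("mi", site).reverse_complement("mi")
        seq = up + site + down
        utr = RnaSequence("ut", seq)
        anchor = len(up) + len(site)
        m = len(mi)
        pairs = [(i, anchor + 1 - i) for i in range(1, m + 1)]
        s = DuplexStructure.from_pairs(pairs, mi, utr, params)
        return zone_for(s, utr), utr, mi

    def test_gc_rich_site(self, params):
        zone, utr, mi = self._fixed_zone(params, "GCGCGCGC", "AU" * 12, "UA" * 12)
        f = compositional_features(zone, utr, mi)
        assert f["gc_target"] == 1.0
        # "GCGCGCGC" contains the CpG dinucleotide (5'-CG-3') three times
        assert f["cpg_target"] == 3
        assert f["gc_upstream50"] == 0.0
        assert f["cpg_upstream"] == 0

    def test_au_site(self, params):
        zone, utr, mi = self._fixed_zone(params, "AUAUAUAU", "GC" * 12, "CG" * 12)
        f = compositional_features(zone, utr, mi)
        assert f["gc_target"] == 0.0
        assert f["cpg_target"] == 0
        assert f["gc_diff_site_flank"] == -1.0

    def test_matches_direct_character_counts(self, params, rng):
        for _ in range(60):
            mi = random_rna(rng, 12, "mi")
            utr = random_rna(rng, 140, "ut")
            anchor = int(rng.integers(40, 100))
            site_lo = anchor - 11
            pairs = []  # synthesise a fully paired register via sequence surgery
            seq = list(utr.residues)
            comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
            for i in range(1, 13):
                seq[anchor - i] = comp[mi[i - 1]]
            utr = RnaSequence("ut", "".join(seq))
            pairs = [(i, anchor + 1 - i) for i in range(1, 13)]
            s = DuplexStructure.from_pairs(pairs, mi, utr, params)
            f = compositional_features(zone_for(s, utr), utr, mi)
            site = utr.residues[site_lo - 1:anchor]
            up20 = utr.residues[max(0, site_lo - 21):site_lo - 1]
            gc = lambda x: sum(c in "GC" for c in x) / len(x) if x else 0.0
            assert f["gc_target"] == pytest.approx(gc(site))
            assert f["cpg_target"] == site.count("CG")
            assert f["cpg_upstream"] == up20.count("CG")
            assert f["gc_diff_site_flank"] == pytest.approx(gc(site) - gc(up20))
            assert f["gc_diff_first_last8"] == pytest.approx(gc(site[:8]) - gc(site[-8:]))

    def test_invariant_under_dna_alphabet_input(self, params):
        """gc_*/cpg_* features are identical for U- and T-encoded input."""
        site = "GCUUCGGC"
        zone_u, utr_u, mi_u = self._fixed_zone(params, site, "AUGC" * 6, "UUAA" * 6)
        zone_t, utr_t, mi_t = self._fixed_zone(
            params, site.replace("U", "T"), "ATGC" * 6, "TTAA" * 6)
        fu = compositional_features(zone_u, utr_u, mi_u)
        ft = compositional_features(zone_t, utr_t, mi_t)
        assert fu == ft


class TestCompactness:
    def test_perfect_duplex_is_one(self, params, rng):
        mi = random_rna(rng, 22, "mi")
        s, _ = perfect_structure(mi, params)
        assert compactness(s, mi) == 1.0

    def test_arithmetic_example(self):
        """22-nt microRNA, 30-nt site, 15 pairs -> 0.5*(15/22 + 15/30)."""
        class Stub:
            n_pairs = 15
            target_footprint = (1, 30)
        mi = RnaSequence("mi", "A" * 22)
        assert compactness(Stub(), mi) == pytest.approx(0.5 * (15 / 22 + 15 / 30))

    def test_zero_pairs_is_zero(self):
        class Stub:
            n_pairs = 0
            target_footprint = (1, 0)
        assert compactness(Stub(), RnaSequence("mi", "A" * 22)) == 0.0

    def test_range_and_monotonicity(self, params, rng):
        prev = None
        mi = random_rna(rng, 22, "mi")
        for n in range(2, 23):
            class Stub:
                n_pairs = n
                target_footprint = (1, 18)  # site shorter than the microRNA
            v = compactness(Stub(), mi)
            assert 0.0 <= v <= 1.0
            if prev is not None:
                assert v >= prev
            prev = v

    def test_short_site_penalty_continuous_at_equal_length(self):
        mi = RnaSequence("mi", "A" * 22)

        def value(ts_len, n):
            class Stub:
                n_pairs = n
                target_footprint = (1, ts_len)
            return compactness(Stub(), mi)

        assert value(22, 18) == pytest.approx(0.5 * (18 / 22 + 18 / 22))
        assert value(21, 18) < value(22, 18)


class TestExtractFeatures:
    def test_default_set_on_perfect_implant(self, params, rng):
        mi = random_rna(rng, 22, "mi")
        s, win = perfect_structure(mi, params)
        utr = RnaSequence("ut", "A" * 30 + win.residues + "A" * 30)
        pairs = [(i, 30 + 22 + 1 - i) for i in range(1, 23)]
        s = DuplexStructure.from_pairs(pairs, mi, utr, params)
        f = extract_features(zone_for(s, utr), utr, mi, DEFAULT_MODEL_FEATURES)
        assert set(f) == set(DEFAULT_MODEL_FEATURES)
        assert f["compactness"] == 1.0
        assert f["seed8_pairings"] == 8

    def test_full_catalogue_cardinality_and_determinism(self, params, rng):
        mi = random_rna(rng, 22, "mi")
        s, _ = random_duplex_structure(mi, rng, params)
        utr = RnaSequence("ut", "A" * 10 + "G" * 200)
        # re-anchor the synthetic window inside a longer UTR
        offset = 20
        pairs = [(i, j + offset) for i, j in s.pairs]
        seq = list(utr.residues)
        win_seq = None
        s2, win = random_duplex_structure(mi, np.random.default_rng(5), params)
        for (i, j) in s2.pairs:
            seq[j + offset - 1] = win[j - 1]
        utr = RnaSequence("ut", "".join(seq))
        s3 = DuplexStructure.from_pairs(
            [(i, j + offset) for i, j in s2.pairs], mi, utr, params)
        zone = zone_for(s3, utr)
        f1 = extract_features(zone, utr, mi)
        f2 = extract_features(zone, utr, mi)
        assert len(f1) == 43
        assert set(f1) == set(CATALOGUE)
        assert f1 == f2

    def test_unknown_feature_rejected(self, params, rng):
        mi = random_rna(rng, 22, "mi")
        s, win = perfect_structure(mi, params)
        with pytest.raises(ValueError):
            extract_features(zone_for(s, win), win, mi, ("no_such_feature",))

    def test_accessibility_absent_by_default(self, params, rng):
        mi = random_rna(rng, 22, "mi")
        s, win = perfect_structure(mi, params)
        with pytest.raises(ValueError):
            extract_features(zone_for(s, win), win, mi, ("accessibility_3_15",))
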