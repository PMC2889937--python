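"""Duplex scoring and anchored minimisation against independent oracles."""
import math

import numpy as np
import pytest

from mirspot.energy import (
    DuplexStructure,
    InvalidStructureError,
    anchor_energy_profile,
    anchored_minimum,
    perfect_complement_energy,
    filter_structure,
    score_structure,
)
from mirspot.sequences import RnaSequence, SequenceError

from conftest import random_rna
from oracles import brute_minimum


class TestSequences:
    def test_t_and_case_normalisation(self):
        seq = RnaSequence("x", "acgt")
        assert seq.residues == "ACGU"

    @pytest.mark.parametrize("bad", ["", "ACGX", "AC GU"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(SequenceError):
            RnaSequence("x", bad)

    def test_reverse_complement(self):
        assert RnaSequence("x", "GGAUC").reverse_complement().residues == "GAUCC"


class TestScoreStructure:
    def test_two_stacked_gc_pairs_closed_form(self, params):
        # 5'GC3' guide vs 3'CG5' target: init + stack(GC,CG), no terminal penalty
        mi = RnaSequence("mi", "GC")
        win = RnaSequence("w", "GC")
        e = score_structure([(1, 2), (2, 1)], mi, win, params)
        assert e == pytest.approx(params.init_energy + params.stack_energy[("GC", "CG")])

    def test_zero_table_scores_zero(self, zero_params, rng):
        mi = random_rna(rng, 8, "mi")
        win = mi.reverse_complement()
        pairs = [(i, 8 + 1 - i) for i in range(1, 9)]
        assert score_structure(pairs, mi, win, zero_params) == 0.0

    def test_matches_term_by_term_resummation(self, params, rng):
        """Random admissible structures re-summed independently term by term."""
        from mirspot.synthetic import random_duplex_structure

        for k in range(50):
            mi = random_rna(rng, 12, "mi")
            structure, win = random_duplex_structure(mi, rng, params)
            pairs = structure.pairs
            # independent oracle: iterate helices and gaps explicitly
            pair_name = lambda i, j: mi[i - 1] + win[j - 1]
            term = lambda i, j: (params.terminal_penalty
                                 if pair_name(i, j) in ("AU", "UA", "GU", "UG") else 0.0)
            expected = params.init_energy
            helix_start = pairs[0]
            for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
                a, b = i2 - i1 - 1, j1 - j2 - 1
                if a == 0 and b == 0:
                    expected += params.stack_energy[(pair_name(i1, j1), pair_name(i2, j2))]
                else:
                    expected += term(*helix_start) + term(i1, j1)
                    if a and b:
                        expected += params.interior_penalty[a + b]
                    else:
                        expected += params.bulge_penalty[max(a, b)]
                    helix_start = (i2, j2)
            expected += term(*helix_start) + term(*pairs[-1])
            assert structure.energy == pytest.approx(expected, abs=1e-9)

    def test_non_pairable_bases_rejected(self, params):
        mi = RnaSequence("mi", "AA")
        win = RnaSequence("w", "AA")
        with pytest.raises(InvalidStructureError):
            score_structure([(1, 2), (2, 1)], mi, win, params)

    def test_loop_exceeding_cap_rejected(self, params):
        mi = RnaSequence("mi", "GC" * 30)
        win = mi.reverse_complement()
        m = len(mi)
        pairs = [(1, m), (2, m - 1), (m - 1, 2), (m, 1)]
        with pytest.raises(InvalidStructureError):
            score_structure(pairs, mi, win, params)

    def test_lonely_pair_rejected(self, params):
        mi = RnaSequence("mi", "GCAGC")
        win = RnaSequence("w", "GCAGC")
        with pytest.raises(InvalidStructureError):
            score_structure([(1, 5), (2, 4), (5, 1)], mi, win, params)

    def test_additive_over_interior_loop(self, params):
        """Two helices joined by an interior loop score as parts plus penalty."""
        mi = RnaSequence("mi", "GCCAGGC")
        win = RnaSequence("w", "GCCAGGC")  # pairs: G:C ... C:G by symmetry
        helix1 = [(1, 7), (2, 6)]
        helix2 = [(6, 2), (7, 1)]
        full = helix1 + helix2
        e_full = score_structure(full, mi, win, params)
        e_1 = score_structure(helix1, mi, win, params)
        e_2 = score_structure(helix2, mi, win, params)
        loop = params.interior_penalty[3 + 3]
        assert e_full == pytest.approx(e_1 + e_2 - params.init_energy + loop)


class TestPerfectComplement:
    def test_homopolymer_closed_form(self, params):
        mi = RnaSequence("mi", "G" * 8)
        e = perfect_complement_energy(mi, params)
        assert e == pytest.approx(params.init_energy + 7 * params.stack_energy[("GC", "GC")])

    def test_zero_table(self, zero_params):
        assert perfect_complement_energy(RnaSequence("mi", "GCGCGCGC"), zero_params) == 0.0

    def test_strictly_negative_for_length_8(self, params, rng):
        for _ in range(30):
            mi = random_rna(rng, int(rng.integers(8, 25)), "mi")
            assert perfect_complement_energy(mi, params) < 0

    def test_global_lower_bound(self, params, rng):
        """E_perfect bounds every admissible anchored energy from below."""
        for _ in range(25):
            mi = random_rna(rng, 8, "mi")
            ep = perfect_complement_energy(mi, params)
            ut = random_rna(rng, 13, "ut")
            prof = anchor_energy_profile(mi, ut, params)
            finite = prof["e_all"][np.isfinite(prof["e_all"])]
            if finite.size:
                assert finite.min() >= ep - 1e-9


class TestFilterStructure:
    def _structure(self, mi, win, pairs, params):
        return DuplexStructure.from_pairs(pairs, mi, win, params)

    def test_perfect_watson_crick_kept(self, params, rng):
        mi = random_rna(rng, 10, "mi")
        win = mi.reverse_complement()
        s = self._structure(mi, win, [(i, 11 - i) for i in range(1, 11)], params)
        assert filter_structure(s)

    def test_gu_in_first_eight_discarded(self, params):
        # third pair is G:U (win position 8 opposite microRNA position 3)
        mi = RnaSequence("mi", "GCGCGCGCGC")
        win = RnaSequence("w", "GCGCGCGUGC")
        pairs = [(i, 11 - i) for i in range(1, 11)]
        s = self._structure(mi, win, pairs, params)
        assert s.gu[2] and sum(s.gu) == 1
        assert not filter_structure(s)

    def test_five_gu_past_position_8_discarded(self, params):
        mi = RnaSequence("mi", "GCGCGCGC" + "G" * 5)
        win = RnaSequence("w", "U" * 5 + "GCGCGCGC")
        pairs = [(i, 14 - i) for i in range(1, 14)]
        s = self._structure(mi, win, pairs, params)
        assert sum(s.gu) == 5 and not any(s.gu[:8])
        assert not filter_structure(s)

    def test_four_gu_past_position_8_kept(self, params):
        mi = RnaSequence("mi", "GCGCGCGCC" + "G" * 4)
        win = RnaSequence("w", "U" * 4 + "GGCGCGCGC")
        pairs = [(i, 14 - i) for i in range(1, 14)]
        s = self._structure(mi, win, pairs, params)
        assert sum(s.gu) == 4
        assert filter_structure(s)


class TestAnchoredMinimum:
    def test_implanted_perfect_complement(self, params, rng):
        mi = random_rna(rng, 10, "mi")
        site = mi.reverse_complement().residues
        utr = RnaSequence("ut", "A" * 12 + site + "A" * 6)
        anchor = 12 + len(site)
        opt = anchored_minimum(mi, utr, anchor, params)
        assert opt.structure is not None
        assert opt.structure.energy == pytest.approx(
            perfect_complement_energy(mi, params), abs=1e-9)
        assert opt.structure.pairs[0] == (1, anchor)

    def test_poly_a_has_no_structure(self, params):
        mi = RnaSequence("mi", "A" * 9)
        utr = RnaSequence("ut", "A" * 20)
        opt = anchored_minimum(mi, utr, 10, params)
        assert opt.structure is None and not opt.seed_flag

    def test_anchor_out_of_range(self, params, rng):
        mi = random_rna(rng, 9, "mi")
        utr = random_rna(rng, 12, "ut")
        with pytest.raises(IndexError):
            anchored_minimum(mi, utr, 13, params)

    def test_matches_exhaustive_enumeration(self, params, rng):
        """DP optimum equals brute-force enumeration on small instances."""
        for _ in range(25):
            mi = random_rna(rng, int(rng.integers(7, 10)), "mi")
            ut = random_rna(rng, int(rng.integers(9, 15)), "ut")
            anchor = int(rng.integers(1, len(ut) + 1))
            best, argmin = brute_minimum(mi, ut, anchor, params)
            opt = anchored_minimum(mi, ut, anchor, params)
            if best is None:
                assert opt.structure is None
            else:
                assert opt.structure.energy == pytest.approx(best[0], abs=1e-9)
                assert opt.structure.n_pairs == best[1]
                assert list(opt.structure.pairs) in argmin

    def test_no_lonely_pairs_returned(self, params, rng):
        for _ in range(40):
            mi = random_rna(rng, 9, "mi")
            ut = random_rna(rng, 14, "ut")
            opt = anchored_minimum(mi, ut, len(ut) // 2, params)
            if opt.structure is None:
                continue
            pairs = opt.structure.pairs
            runs = []
            run = 1
            for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
                if i2 == i1 + 1 and j2 == j1 - 1:
                    run += 1
                else:
                    runs.append(run)
                    run = 1
            runs.append(run)
            assert min(runs) >= 2

    def test_stacking_monotonicity(self, params, rng):
        """Extending a helix by a stacked Watson-Crick pair lowers the energy."""
        wc = {"A": "U", "C": "G", "G": "C", "U": "A"}
        for _ in range(40):
            mi = random_rna(rng, 10, "mi")
            win = mi.reverse_complement()
            m = len(mi)
            k = int(rng.integers(3, m))
            shorter = [(i, m + 1 - i) for i in range(1, k)]
            longer = shorter + [(k, m + 1 - k)]
            assert (score_structure(longer, mi, win, params)
                    < score_structure(shorter, mi, win, params))

    def test_profile_consistent_with_exact_dp(self, params, rng):
        """Fast all-anchors profile equals per-anchor exact optimisation."""
        for _ in range(10):
            mi = random_rna(rng, int(rng.integers(7, 11)), "mi")
            ut = random_rna(rng, 25, "ut")
            prof = anchor_energy_profile(mi, ut, params)
            for a in range(1, len(ut) + 1):
                opt = anchored_minimum(mi, ut, a, params)
                if opt.structure is None:
                    assert math.isinf(prof["e_all"][a - 1])
                else:
                    assert prof["e_all"][a - 1] == pytest.approx(
                        opt.structure.energy, abs=1e-9)
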