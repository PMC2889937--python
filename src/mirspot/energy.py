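"""Intermolecular microRNA:mRNA duplex scoring and anchored energy minimisation.

The energy model is a self-contained nearest-neighbor scheme over the six
canonical RNA pairs (Watson-Crick plus G:U wobble):

    E = init + sum(stacking terms) + sum(bulge/interior penalties)
        + terminal AU/GU penalty at both ends of every maximal helix

Admissible structures are antiparallel and non-crossing, every maximal helix
has length >= 2 (no lonely pairs), no G:U occurs among the first eight pairs,
and fewer than five G:U pairs occur in total.  The bundled parameter table
(``data/nn_params_v1.tsv``) uses Turner-style Watson-Crick stacking values
with affine loop penalties; only relative energies matter downstream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import _kernels
from .sequences import BASES, RnaSequence

PAIR_TYPES = ("AU", "UA", "GC", "CG", "GU", "UG")
_PAIR_INDEX = {p: i for i, p in enumerate(PAIR_TYPES)}
#: minimum length of a perfect 5'-end helix that counts as a seed region
SEED_LENGTH = 7


class InvalidStructureError(ValueError):
    """Raised when a pair list violates the duplex admissibility rules."""


@dataclass(frozen=True)
class EnergyParameters:
    """Nearest-neighbor duplex parameters (kcal/mol).

    ``stack_energy`` maps ordered adjacent pair-of-pairs (5'-side pair first,
    each pair written as guide base + target base) to stacking energies.
    ``bulge_penalty[l]`` and ``interior_penalty[l]`` are indexed by unpaired
    length (one-sided, respectively total two-sided).
    """

    stack_energy: dict
    bulge_penalty: np.ndarray
    interior_penalty: np.ndarray
    init_energy: float
    terminal_penalty: float
    max_loop_side: int
    version: str

    def __post_init__(self):
        for (p1, p2), v in self.stack_energy.items():
            if p1 not in _PAIR_INDEX or p2 not in _PAIR_INDEX:
                raise ValueError(f"unknown pair type in stack table: {(p1, p2)}")
            if v > 0:
                raise ValueError("stacking energies must be <= 0")
        if np.any(self.bulge_penalty[1:] < 0) or np.any(self.interior_penalty[2:] < 0):
            raise ValueError("loop penalties must be non-negative")

    @property
    def stack_matrix(self) -> np.ndarray:
        m = np.zeros((6, 6))
        for (p1, p2), v in self.stack_energy.items():
            m[_PAIR_INDEX[p1], _PAIR_INDEX[p2]] = v
        return m

    @property
    def terminal_by_type(self) -> np.ndarray:
        return self.terminal_penalty * _kernels.TERM_MASK

    def affine_loop_coefficients(self) -> tuple[float, float, float, float]:
        """(b0, b1, i0, i1) if both penalty tables are affine, else raises."""
        bd = np.diff(self.bulge_penalty[1:])
        idd = np.diff(self.interior_penalty[2:])
        if bd.size and not np.allclose(bd, bd[0]):
            raise ValueError("bulge penalties are not affine in length")
        if idd.size and not np.allclose(idd, idd[0]):
            raise ValueError("interior penalties are not affine in length")
        b1 = float(bd[0]) if bd.size else 0.0
        i1 = float(idd[0]) if idd.size else 0.0
        return float(self.bulge_penalty[1]), b1, float(self.interior_penalty[2]), i1


def load_default_parameters() -> EnergyParameters:
    """Load the bundled versioned parameter table."""
    text = resources.files("mirspot.data").joinpath("nn_params_v1.tsv").read_text()
    return parse_parameter_table(text)


def parse_parameter_table(text: str) -> EnergyParameters:
    stack: dict = {}
    bulge: dict = {}
    interior: dict = {}
    scalars: dict = {}
    version = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        kind, k1, k2, value = (line.split("\t") + [""] * 4)[:4]
        if kind == "version":
            version = k1
        elif kind == "stack":
            stack[(k1, k2)] = float(value)
        elif kind == "bulge":
            bulge[int(k1)] = float(value)
        elif kind == "interior":
            interior[int(k1)] = float(value)
        else:
            scalars[kind] = float(value)
    if version is None:
        raise ValueError("parameter table lacks a version record")
    missing = {(a, b) for a in PAIR_TYPES for b in PAIR_TYPES} - set(stack)
    if missing:
        raise ValueError(f"stack table incomplete; missing {sorted(missing)[:3]} ...")
    max_loop = int(scalars["max_loop_side"])
    barr = np.zeros(max_loop + 1)
    for ell in range(1, max_loop + 1):
        barr[ell] = bulge[ell]
    iarr = np.zeros(2 * max_loop + 1)
    for tot in range(2, 2 * max_loop + 1):
        iarr[tot] = interior[tot]
    return EnergyParameters(
        stack_energy=stack,
        bulge_penalty=barr,
        interior_penalty=iarr,
        init_energy=scalars["init"],
        terminal_penalty=scalars["terminal_au_gu"],
        max_loop_side=max_loop,
        version=version,
    )


@dataclass(frozen=True)
class DuplexStructure:
    """An intermolecular base-pairing pattern with its free energy.

    ``pairs`` holds 1-based (microRNA position from its 5' end, target
    position) tuples with microRNA positions strictly increasing and target
    positions strictly decreasing (antiparallel).  ``gu`` flags which pairs
    are G:U wobbles.
    """

    pairs: tuple
    energy: float
    gu: tuple = ()

    @classmethod
    def from_pairs(cls, pairs, mirna: RnaSequence, window: RnaSequence,
                   params: EnergyParameters) -> "DuplexStructure":
        pairs = tuple((int(i), int(j)) for i, j in pairs)
        energy = score_structure(pairs, mirna, window, params)
        gu = tuple(
            (mirna[i - 1], window[j - 1]) in {("G", "U"), ("U", "G")}
            for i, j in pairs
        )
        return cls(pairs=pairs, energy=energy, gu=gu)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def anchor(self) -> int:
        """Target position paired with the 5'-most paired microRNA base."""
        return self.pairs[0][1]

    @property
    def target_footprint(self) -> tuple:
        """1-based inclusive (start, end) of the paired target span."""
        return (self.pairs[-1][1], self.pairs[0][1])

    def has_seed_region(self) -> bool:
        """Perfect 5'-end pairing of >= 7 consecutive nucleotides from position 1."""
        if len(self.pairs) < SEED_LENGTH or self.pairs[0][0] != 1:
            return False
        t0 = self.pairs[0][1]
        return all(
            self.pairs[k] == (k + 1, t0 - k) for k in range(SEED_LENGTH)
        )


@dataclass(frozen=True)
class AnchoredOptimum:
    """Best admissible duplex whose 5'-most pairing sits at ``anchor``."""

    anchor: int
    structure: DuplexStructure | None
    seed_flag: bool

    @property
    def energy(self) -> float:
        return self.structure.energy if self.structure is not None else 0.0


def _check_pairs(pairs, mirna, window, params):
    if not pairs:
        raise InvalidStructureError("empty pair list")
    m, L = len(mirna), len(window)
    for i, j in pairs:
        if not (1 <= i <= m) or not (1 <= j <= L):
            raise InvalidStructureError(f"pair {(i, j)} out of range")
        if (mirna[i - 1], window[j - 1]) not in {
            ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")
        }:
            raise InvalidStructureError(
                f"bases {mirna[i-1]}:{window[j-1]} at {(i, j)} cannot pair"
            )
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 <= i1 or j2 >= j1:
            raise InvalidStructureError("pairs must be antiparallel and non-crossing")
        a, b = i2 - i1 - 1, j1 - j2 - 1
        if a > params.max_loop_side or b > params.max_loop_side:
            raise InvalidStructureError(
                f"unpaired run of {max(a, b)} exceeds max_loop_side={params.max_loop_side}"
            )
    # no lonely pairs: every maximal helix must have >= 2 stacked pairs
    run = 1
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 == i1 + 1 and j2 == j1 - 1:
            run += 1
        else:
            if run < 2:
                raise InvalidStructureError("helix of length 1 (lonely pair)")
            run = 1
    if run < 2:
        raise InvalidStructureError("helix of length 1 (lonely pair)")


def score_structure(pairs, mirna: RnaSequence, window: RnaSequence,
                    params: EnergyParameters) -> float:
    """Explicit scoring function: init + stacks + loop penalties + terminals."""
    pairs = [(int(i), int(j)) for i, j in pairs]
    _check_pairs(pairs, mirna, window, params)

    def ptype(i, j):
        return _PAIR_INDEX[mirna[i - 1] + window[j - 1]]

    term = params.terminal_by_type
    stack = params.stack_matrix
    e = params.init_energy + term[ptype(*pairs[0])]
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        a, b = i2 - i1 - 1, j1 - j2 - 1
        if a == 0 and b == 0:
            e += stack[ptype(i1, j1), ptype(i2, j2)]
        else:
            if a == 0:
                pen = params.bulge_penalty[b]
            elif b == 0:
                pen = params.bulge_penalty[a]
            else:
                pen = params.interior_penalty[a + b]
            e += term[ptype(i1, j1)] + pen + term[ptype(i2, j2)]
    e += term[ptype(*pairs[-1])]
    return float(e)


def perfect_complement_energy(mirna: RnaSequence, params: EnergyParameters) -> float:
    """Energy of the fully Watson-Crick duplex against the reverse complement.

    This is the energy floor used to normalise candidate-zone thresholds.
    """
    m = len(mirna)
    if m < 2:
        raise ValueError("microRNA too short for a duplex")
    window = mirna.reverse_complement()
    pairs = [(i, m + 1 - i) for i in range(1, m + 1)]
    return score_structure(pairs, mirna, window, params)


def filter_structure(structure: DuplexStructure,
                     mirna: RnaSequence | None = None,
                     window: RnaSequence | None = None) -> bool:
    """G:U discard rules: keep (True) unless a G:U occurs among the first
    eight pairs or the duplex carries five or more G:U pairs in total."""
    gu = structure.gu
    if not gu and structure.pairs:
        if mirna is None or window is None:
            raise ValueError("structure lacks G:U flags; pass mirna and window")
        gu = tuple(
            (mirna[i - 1], window[j - 1]) in {("G", "U"), ("U", "G")}
            for i, j in structure.pairs
        )
    if any(gu[:8]):
        return False
    if sum(gu) >= 5:
        return False
    return True


def span_3prime(mirna: RnaSequence) -> int:
    """Window extent upstream of the anchor searched for 3'-side pairing."""
    return len(mirna) + 15


def _kernel_args(params: EnergyParameters):
    return (
        params.stack_matrix,
        params.bulge_penalty,
        params.interior_penalty,
        params.init_energy,
        params.terminal_by_type,
        params.max_loop_side,
    )


def anchored_minimum(mirna: RnaSequence, utr: RnaSequence, anchor: int,
                     params: EnergyParameters, *, require_seed: bool = False,
                     first_i_max: int = -1) -> AnchoredOptimum:
    """Minimum-energy admissible duplex anchored at ``anchor`` (1-based).

    The anchor is the mRNA position paired with the 5'-most paired microRNA
    nucleotide; the search window is [anchor - span_3prime, anchor].
    ``require_seed`` restricts the search to structures beginning with the
    perfect 7-nt 5'-end helix (used for seed-preference pruning).
    """
    if not 1 <= anchor <= len(utr):
        raise IndexError(f"anchor {anchor} outside UTR of length {len(utr)}")
    stack, bulge, interior, init_e, term6, max_loop = _kernel_args(params)
    found, _energy, pairs = _kernels.exact_anchored_dp(
        mirna.codes(), utr.codes(), anchor - 1, span_3prime(mirna),
        stack, bulge, interior, init_e, term6, max_loop,
        require_seed, first_i_max,
    )
    if not found:
        return AnchoredOptimum(anchor=anchor, structure=None, seed_flag=False)
    structure = DuplexStructure.from_pairs(
        [(int(i) + 1, int(j) + 1) for i, j in pairs], mirna, utr, params
    )
    return AnchoredOptimum(
        anchor=anchor, structure=structure, seed_flag=structure.has_seed_region()
    )


def seed_match_positions(mirna: RnaSequence, utr: RnaSequence) -> np.ndarray:
    """Boolean mask over anchors where a perfect 7-nt 5'-end helix is possible."""
    wc = {"A": "U", "C": "G", "G": "C", "U": "A"}
    L = len(utr)
    out = np.zeros(L, dtype=bool)
    for a in range(SEED_LENGTH - 1, L):
        ok = True
        for k in range(SEED_LENGTH):
            if utr[a - k] != wc[mirna[k]]:
                ok = False
                break
        out[a] = ok
    return out


def anchor_energy_profile(mirna: RnaSequence, utr: RnaSequence,
                          params: EnergyParameters):
    """Per-anchor minimum energies for all UTR positions.

    Returns a dict of arrays (length |UTR|, math.inf where no structure):
      ``e_all``   minimum admissible anchored energy;
      ``e_12``    minimum over structures starting at microRNA position 1 or 2;
      ``e_seed``  minimum over seed-region structures (inf where no seed);
      ``seed_ok`` boolean mask of anchors admitting a seed-region helix.
    """
    mi, ut = mirna.codes(), utr.codes()
    span = span_3prime(mirna)
    stack, bulge, interior, init_e, term6, max_loop = _kernel_args(params)
    try:
        b0, b1, ic0, ic1 = params.affine_loop_coefficients()
        if len(mirna) > max_loop - 14:
            raise ValueError("window exceeds loop cap")
        e_all, e_12 = _kernels.profile_dp(
            mi, ut, span, stack, b0, b1, ic0, ic1, init_e, term6
        )
        e_all = np.where(e_all > _kernels.BIG, math.inf, e_all)
        e_12 = np.where(e_12 > _kernels.BIG, math.inf, e_12)
    except ValueError:
        # general (non-affine) tables: per-anchor exact DP
        L = len(utr)
        e_all = np.full(L, math.inf)
        e_12 = np.full(L, math.inf)
        for a0 in range(L):
            found, e, _ = _kernels.exact_anchored_dp(
                mi, ut, a0, span, stack, bulge, interior, init_e, term6,
                max_loop, False, -1)
            if found:
                e_all[a0] = e
            found, e, _ = _kernels.exact_anchored_dp(
                mi, ut, a0, span, stack, bulge, interior, init_e, term6,
                max_loop, False, 1)
            if found:
                e_12[a0] = e

    seed_ok = seed_match_positions(mirna, utr)
    e_seed = np.full(len(utr), math.inf)
    for a0 in np.flatnonzero(seed_ok):
        found, e, _ = _kernels.exact_anchored_dp(
            mi, ut, int(a0), span, stack, bulge, interior, init_e, term6,
            max_loop, True, -1)
        if found:
            e_seed[a0] = e
    return {"e_all": e_all, "e_12": e_12, "e_seed": e_seed, "seed_ok": seed_ok}
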