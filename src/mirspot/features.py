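"""Duplex, positional and compositional features of a candidate zone.

The catalogue covers base-pairing extent, G:U usage, per-strand bulge
statistics, target-site position and nucleotide anchors, G+C/CpG composition
of the site and its flanks, and the compactness measure (mean of
pairings/microRNA-length and pairings/site-length, penalised when the site is
shorter than the microRNA).  RISC-accessibility features require an
intramolecular folding backend and are only available through a registered
hook; they are absent by default.
"""
from __future__ import annotations

import math

import numpy as np

from .energy import DuplexStructure
from .sequences import RnaSequence

#: canonical feature names (full catalogue computed by extract_features)
CATALOGUE = (
    "seed8_pairings", "gc_target", "pairings_3prime_8", "consecutive_3prime_2gap",
    "cpg_target", "gc_ratio_mirna_target", "compactness", "t9_anchor",
    "longest_stretch", "mi_bulges_len3", "t1_sw_anchor", "total_pairings",
    "t_bulges_len7plus", "t1_anchor", "mi_bulges_len2", "cpg_upstream",
    "t_bulges_len1", "t_bulge_total_len", "target_len", "mi_bulge_total_len",
    "utr_position_bin", "symmetric_bulges", "gc_upstream50", "t_bulge_count",
    "t_second_largest_bulge", "t_bulge_mean_len", "t9_sw_anchor",
    "binding_asymmetry", "t_bulges_len2", "gu_total", "t_bulges_len4",
    "gc_diff_first_last8", "cpg_downstream", "mi_bulges_len1",
    "mi_second_largest_bulge", "mi_bulge_count", "mi_bulges_len5",
    "t_bulges_len3", "gc_diff_site_flank", "t_bulges_len5", "mi_bulges_len4",
    "gc_downstream50", "t_bulges_len6",
)

#: the seven-feature model subset selected by correlation-based selection
DEFAULT_MODEL_FEATURES = (
    "compactness", "gc_ratio_mirna_target", "longest_stretch",
    "binding_asymmetry", "gc_target", "seed8_pairings", "utr_position_bin",
)

#: numeric encoding of nucleotide anchor features
NUCLEOTIDE_CODE = {"none": 0.0, "A": 1.0, "C": 2.0, "G": 3.0, "U": 4.0}

#: optional accessibility backends, keyed by feature name
_ACCESSIBILITY_HOOKS: dict = {}


def register_accessibility_hook(name: str, func) -> None:
    """Register an intramolecular-folding backend for an accessibility feature
    (``accessibility_3_15`` or ``accessibility_30_30``).  ``func(zone, utr,
    mirna) -> float``."""
    if name not in ("accessibility_3_15", "accessibility_30_30"):
        raise ValueError(f"unknown accessibility feature {name!r}")
    _ACCESSIBILITY_HOOKS[name] = func


def _gc(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(b in "GC" for b in seq) / len(seq)


def _cpg(seq: str) -> int:
    return seq.count("CG")


def pairing_features(structure: DuplexStructure, mirna: RnaSequence) -> dict:
    """Base-pairing extent features of the hybrid."""
    pairs = structure.pairs
    m = len(mirna)
    mi_pos = [i for i, _ in pairs]
    paired = set(mi_pos)

    seed8 = sum(i <= 8 for i in mi_pos)
    three8 = sum(i > m - 8 for i in mi_pos)

    # run from the 3'-most paired base toward 5', allowing two unpaired
    # microRNA positions in total
    consec = 0
    if pairs:
        gaps = 0
        for q in range(max(mi_pos), 0, -1):
            if q in paired:
                consec += 1
            else:
                gaps += 1
                if gaps > 2:
                    break

    longest = run = 0
    for k in range(len(pairs)):
        if k and pairs[k][0] == pairs[k - 1][0] + 1 and pairs[k][1] == pairs[k - 1][1] - 1:
            run += 1
        else:
            run = 1
        longest = max(longest, run)

    t_lo, t_hi = (structure.target_footprint if pairs else (1, 0))
    paired5 = sum(i <= 8 for i in mi_pos)
    paired3 = sum(i > m - 8 for i in mi_pos)
    if paired5 == 0:
        asym = float(paired3 + 1)  # pseudocount: ratio undefined at 0 denominator
    else:
        asym = paired3 / paired5

    return {
        "seed8_pairings": float(seed8),
        "pairings_3prime_8": float(three8),
        "consecutive_3prime_2gap": float(consec),
        "longest_stretch": float(longest),
        "target_len": float(t_hi - t_lo + 1),
        "total_pairings": float(len(pairs)),
        "gu_total": float(sum(structure.gu)),
        "binding_asymmetry": float(asym),
    }


def _strand_bulges(positions: list[int], descending: bool = False) -> list[int]:
    """Lengths of maximal unpaired runs strictly between paired positions."""
    if descending:
        positions = positions[::-1]
    return [b - a - 1 for a, b in zip(positions, positions[1:]) if b - a > 1]


def bulge_features(structure: DuplexStructure) -> dict:
    """Per-strand bulge counts, lengths, size histograms and symmetric bulges.

    A bulge is a maximal run of unpaired nucleotides strictly between two
    paired positions of one strand; an interior loop therefore contributes a
    bulge to each strand, and a symmetric bulge is an inter-pair gap with
    equal unpaired counts (>= 1) on both strands.
    """
    pairs = structure.pairs
    mi_b = _strand_bulges([i for i, _ in pairs])
    t_b = _strand_bulges([j for _, j in pairs], descending=True)
    symmetric = sum(
        1 for (i1, j1), (i2, j2) in zip(pairs, pairs[1:])
        if i2 - i1 - 1 == j1 - j2 - 1 >= 1
    )

    def second_largest(bulges):
        return float(sorted(bulges)[-2]) if len(bulges) >= 2 else 0.0

    out = {
        "mi_bulge_count": float(len(mi_b)),
        "t_bulge_count": float(len(t_b)),
        "mi_bulge_total_len": float(sum(mi_b)),
        "t_bulge_total_len": float(sum(t_b)),
        "mi_second_largest_bulge": second_largest(mi_b),
        "t_second_largest_bulge": second_largest(t_b),
        "t_bulge_mean_len": float(np.mean(t_b)) if t_b else 0.0,
        "symmetric_bulges": float(symmetric),
        "t_bulges_len7plus": float(sum(b >= 7 for b in t_b)),
    }
    for ell in range(1, 6):
        out[f"mi_bulges_len{ell}"] = float(mi_b.count(ell))
    for ell in range(1, 7):
        out[f"t_bulges_len{ell}"] = float(t_b.count(ell))
    return out


def _register_position(pairs, mi_pos: int) -> int | None:
    """Target position opposite a microRNA position along the pairing register.

    Unpaired positions are projected from the nearest 5'-side pair (falling
    back to the nearest 3'-side pair for the microRNA 5' terminus).
    """
    exact = {i: j for i, j in pairs}
    if mi_pos in exact:
        return exact[mi_pos]
    before = [(i, j) for i, j in pairs if i < mi_pos]
    if before:
        q, tq = before[-1]
        return tq - (mi_pos - q)
    after = [(i, j) for i, j in pairs if i > mi_pos]
    if after:
        q, tq = after[0]
        return tq + (q - mi_pos)
    return None


def positional_features(zone, utr: RnaSequence, mirna: RnaSequence) -> dict:
    """Target-site position within the UTR and t1/t9 anchor nucleotides."""
    anchor = zone.representative_anchor
    L = len(utr)
    position_bin = min(100, max(1, math.ceil(100 * anchor / L)))
    t_lo, t_hi = zone.representative.target_footprint
    out = {"utr_position_bin": float(position_bin)}
    for mi_pos, name in ((1, "t1"), (9, "t9")):
        t = _register_position(zone.representative.pairs, mi_pos)
        if t is None or not (t_lo <= t <= t_hi) or not (1 <= t <= L):
            base = "none"
        else:
            base = utr[t - 1]
        out[f"{name}_anchor"] = NUCLEOTIDE_CODE[base]
        # S/W lettering follows the training convention: S = A or U
        out[f"{name}_sw_anchor"] = 1.0 if base in ("A", "U") else 0.0
    return out


def compositional_features(zone, utr: RnaSequence, mirna: RnaSequence) -> dict:
    """G+C content and CpG counts of the site and its flanking regions."""
    t_lo, t_hi = zone.representative.target_footprint
    seq = utr.residues
    site = seq[t_lo - 1:t_hi]
    up50 = seq[max(0, t_lo - 51):t_lo - 1]
    down50 = seq[t_hi:t_hi + 50]
    up20 = seq[max(0, t_lo - 21):t_lo - 1]
    down20 = seq[t_hi:t_hi + 20]
    gc_site = _gc(site)
    gc_mi = _gc(mirna.residues)
    if gc_site > 0:
        ratio = gc_mi / gc_site
    else:
        # treat a G+C-free site as carrying half a G/C base
        ratio = gc_mi * 2 * len(site)
    return {
        "gc_target": gc_site,
        "gc_upstream50": _gc(up50),
        "gc_downstream50": _gc(down50),
        "gc_ratio_mirna_target": ratio,
        "gc_diff_site_flank": gc_site - _gc(up20),
        "gc_diff_first_last8": _gc(site[:8]) - _gc(site[-8:]),
        "cpg_target": float(_cpg(site)),
        "cpg_upstream": float(_cpg(up20)),
        "cpg_downstream": float(_cpg(down20)),
    }


def compactness(structure: DuplexStructure, mirna: RnaSequence) -> float:
    """Mean of pairings/microRNA-length and pairings/site-length, in [0, 1].

    1 corresponds to perfect complementarity (every nucleotide of both
    strands paired).  When the target site is shorter than the microRNA the
    mean is scaled by tsLen/miRLen, which preserves the range and continuity
    at tsLen == miRLen.
    """
    n = structure.n_pairs
    if n == 0:
        return 0.0
    t_lo, t_hi = structure.target_footprint
    ts_len = t_hi - t_lo + 1
    mir_len = len(mirna)
    value = 0.5 * (n / mir_len + n / ts_len)
    if ts_len < mir_len:
        value *= ts_len / mir_len
    return float(value)


def extract_features(zone, utr: RnaSequence, mirna: RnaSequence,
                     feature_set=CATALOGUE) -> dict:
    """Compute the requested features for a zone's representative duplex."""
    values: dict = {}
    values.update(pairing_features(zone.representative, mirna))
    values.update(bulge_features(zone.representative))
    values.update(positional_features(zone, utr, mirna))
    values.update(compositional_features(zone, utr, mirna))
    values["compactness"] = compactness(zone.representative, mirna)
    for name, func in _ACCESSIBILITY_HOOKS.items():
        values[name] = float(func(zone, utr, mirna))
    unknown = [f for f in feature_set if f not in values]
    if unknown:
        raise ValueError(f"unknown or unavailable feature(s): {unknown}")
    return {f: values[f] for f in feature_set}
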