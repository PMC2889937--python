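"""Seeded generators for every input class the pipeline consumes.

The corpus generator emulates 3'UTR/microRNA FASTA input with implanted
complementarity sites of controlled quality, multi-species aligned copies
with controlled conservation, labeled feature tables with controlled class
separation, and proteomics-style fold-change tables.  Background sequence is
i.i.d. with configurable G+C content (optionally first-order Markov); all
generators are bit-reproducible given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import DuplexStructure, EnergyParameters
from .features import DEFAULT_MODEL_FEATURES
from .pipeline import AlignedUtrSet
from .selection import LabeledTable
from .sequences import BASES, COMPLEMENT, RnaSequence, reverse_complement

IMPLANT_QUALITIES = ("perfect", "seed_only", "compensatory_3prime", "shuffled")


@dataclass(frozen=True)
class Implant:
    utr_index: int
    mirna_index: int
    anchor: int  # 1-based UTR position paired with microRNA position 1
    quality: str = "perfect"

    def __post_init__(self):
        if self.quality not in IMPLANT_QUALITIES:
            raise ValueError(f"unknown implant quality {self.quality!r}")


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic corpus and tables."""

    seed: int = 0
    n_utrs: int = 20
    utr_length: tuple = (80, 160)
    gc_background: float = 0.5
    n_mirnas: int = 5
    mirna_length: int = 22
    implants: list = field(default_factory=list)
    markov1: bool = False
    # conservation plan
    n_species: int = 5
    mutation_rate: float = 0.05
    species: tuple = ("sp1", "sp2", "sp3", "sp4", "sp5")
    # labeled-table plan: per-feature mean shift of the positive class
    n_rows: int = 400
    feature_names: tuple = DEFAULT_MODEL_FEATURES
    mean_shift: dict = field(default_factory=dict)
    noise_sd: float = 1.0

    def __post_init__(self):
        if not 0 < self.gc_background < 1:
            raise ValueError("gc_background must lie in (0, 1)")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")


#: moderate class separation used when no explicit shift plan is given
DEFAULT_MEAN_SHIFT = {
    "compactness": 1.0,
    "gc_ratio_mirna_target": 0.6,
    "longest_stretch": 0.6,
    "binding_asymmetry": 0.4,
    "gc_target": 0.4,
    "seed8_pairings": 0.8,
    "utr_position_bin": 0.0,
}


def _random_seq(rng: np.random.Generator, length: int, gc: float,
                markov1: bool = False) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if not markov1:
        return "".join(BASES[k] for k in rng.choice(4, size=length, p=p))
    # mild first-order structure: favour staying within the S/W class
    stay = 0.6
    out = [int(rng.choice(4, p=p))]
    for _ in range(length - 1):
        prev_gc = BASES[out[-1]] in "GC"
        cond = p.copy()
        mask = np.array([b in "GC" for b in BASES])
        cond[mask == prev_gc] *= stay / cond[mask == prev_gc].sum()
        cond[mask != prev_gc] *= (1 - stay) / cond[mask != prev_gc].sum()
        out.append(int(rng.choice(4, p=cond / cond.sum())))
    return "".join(BASES[k] for k in out)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving dinucleotide counts."""
    if len(seq) < 3:
        return seq
    for _ in range(100):
        edges: dict = {b: [] for b in set(seq)}
        for a, b in zip(seq, seq[1:]):
            edges[a].append(b)
        last = seq[-1]
        # randomise, then check the Euler path condition by rebuilding
        for b in edges:
            order = rng.permutation(len(edges[b]))
            edges[b] = [edges[b][k] for k in order]
        walk = [seq[0]]
        pos = {b: 0 for b in edges}
        ok = True
        for _step in range(len(seq) - 1):
            cur = walk[-1]
            if pos[cur] >= len(edges[cur]):
                ok = False
                break
            walk.append(edges[cur][pos[cur]])
            pos[cur] += 1
        if ok and len(walk) == len(seq) and walk[-1] == last:
            return "".join(walk)
    return seq  # fall back to the original on repeated failure


def _implant_site(mirna: RnaSequence, quality: str,
                  rng: np.random.Generator, gc: float) -> str:
    """Target-site sequence (5'->3') whose 3' end pairs microRNA position 1."""
    m = len(mirna)
    if quality == "perfect":
        return reverse_complement(mirna.residues)
    if quality == "seed_only":
        head = _random_seq(rng, m - 8, gc)
        return head + reverse_complement(mirna.residues[:8])
    if quality == "compensatory_3prime":
        # >= 10-nt complementary 3' block of the microRNA, mismatched seed
        block = reverse_complement(mirna.residues[9:])
        seed_len = 9
        mism = []
        for k in range(seed_len):
            wc = COMPLEMENT[mirna.residues[k]]
            choices = [b for b in BASES if b != wc]
            mism.append(choices[int(rng.integers(0, 3))])
        return block + "".join(reversed(mism))
    if quality == "shuffled":
        return dinucleotide_shuffle(reverse_complement(mirna.residues), rng)
    raise ValueError(f"unknown implant quality {quality!r}")


@dataclass
class SyntheticCorpus:
    mirnas: list
    utrs: list
    truth: pd.DataFrame  # utr_id, start, end, mirna_id, anchor, quality
    alignments: dict  # utr_id -> AlignedUtrSet


def generate_corpus(spec: FixtureSpec) -> SyntheticCorpus:
    """Random UTRs and microRNAs with implanted sites and aligned species copies.

    Implant anchors give the UTR position paired with microRNA position 1
    (the 3' end of the site); the truth table records the implanted interval.
    """
    rng = np.random.default_rng(spec.seed)
    mirnas = [
        RnaSequence(f"mir-{k + 1}", _random_seq(rng, spec.mirna_length,
                                                spec.gc_background))
        for k in range(spec.n_mirnas)
    ]
    utr_seqs = [
        list(_random_seq(rng, int(rng.integers(spec.utr_length[0],
                                               spec.utr_length[1] + 1)),
                         spec.gc_background, spec.markov1))
        for _ in range(spec.n_utrs)
    ]
    truth_rows = []
    occupied: dict = {}
    for imp in spec.implants:
        mirna = mirnas[imp.mirna_index]
        site = _implant_site(mirna, imp.quality, rng, spec.gc_background)
        start = imp.anchor - len(site) + 1
        seq = utr_seqs[imp.utr_index]
        if start < 1 or imp.anchor > len(seq):
            raise ValueError(
                f"implant at anchor {imp.anchor} does not fit UTR {imp.utr_index}"
            )
        span = set(range(start, imp.anchor + 1))
        if occupied.setdefault(imp.utr_index, set()) & span:
            raise ValueError(f"overlapping implants in UTR {imp.utr_index}")
        occupied[imp.utr_index] |= span
        seq[start - 1:imp.anchor] = list(site)
        truth_rows.append({
            "utr_id": f"utr-{imp.utr_index + 1}",
            "start": start,
            "end": imp.anchor,
            "mirna_id": mirna.id,
            "anchor": imp.anchor,
            "quality": imp.quality,
        })
    utrs = [RnaSequence(f"utr-{k + 1}", "".join(s)) for k, s in enumerate(utr_seqs)]
    truth = pd.DataFrame(
        truth_rows,
        columns=["utr_id", "start", "end", "mirna_id", "anchor", "quality"],
    )
    alignments = {
        utr.id: _aligned_copies(utr, spec, rng) for utr in utrs
    } if spec.n_species >= 2 else {}
    return SyntheticCorpus(mirnas=mirnas, utrs=utrs, truth=truth,
                           alignments=alignments)


def _aligned_copies(utr: RnaSequence, spec: FixtureSpec,
                    rng: np.random.Generator) -> AlignedUtrSet:
    """Species rows derived from the reference by i.i.d. substitution."""
    species = list(spec.species[:spec.n_species])
    rows = {species[0]: utr.residues}
    for sp in species[1:]:
        chars = list(utr.residues)
        hits = np.flatnonzero(rng.random(len(chars)) < spec.mutation_rate)
        for k in hits:
            choices = [b for b in BASES if b != chars[k]]
            chars[k] = choices[int(rng.integers(0, 3))]
        rows[sp] = "".join(chars)
    return AlignedUtrSet(transcript_id=utr.id, rows=rows, reference=species[0])


def generate_labeled_table(spec: FixtureSpec) -> LabeledTable:
    """Two-class Gaussian feature table with configured mean shifts.

    Negative rows are N(0, noise_sd) per feature; positive rows are shifted
    by the per-feature mean shift (in units of noise_sd).
    """
    if spec.n_rows <= 0:
        raise ValueError("n_rows must be positive")
    rng = np.random.default_rng(spec.seed)
    shift = spec.mean_shift or DEFAULT_MEAN_SHIFT
    names = list(spec.feature_names)
    n = spec.n_rows
    n_pos = n // 2
    labels = np.concatenate([np.ones(n_pos, dtype=int),
                             np.zeros(n - n_pos, dtype=int)])
    X = rng.normal(0.0, spec.noise_sd, size=(n, len(names)))
    for j, name in enumerate(names):
        X[:n_pos, j] += shift.get(name, 0.0) * spec.noise_sd
    perm = rng.permutation(n)
    frame = pd.DataFrame(X[perm], columns=names)
    return LabeledTable(frame, labels[perm])


def generate_psilac_table(predictions: list, fraction_down: float,
                          seed: int = 0, cutoff: float = -0.1) -> pd.DataFrame:
    """Fold-change table in which the stated fraction of predicted
    interactions is down-regulated past the cutoff."""
    if not 0 <= fraction_down <= 1:
        raise ValueError("fraction_down must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    interactions = sorted({(r.utr_id, r.mirna_id) for r in predictions})
    rows = []
    for gene, mirna in interactions:
        if rng.random() < fraction_down:
            lfc = cutoff - abs(rng.normal(0.4, 0.3))
        else:
            lfc = cutoff + abs(rng.normal(0.3, 0.25)) + 1e-6
        rows.append({"gene": gene, "mirna": mirna, "log2fc": lfc})
    return pd.DataFrame(rows, columns=["gene", "mirna", "log2fc"])


def random_duplex_structure(mirna: RnaSequence, rng: np.random.Generator,
                            params: EnergyParameters,
                            max_gap: int = 8) -> tuple:
    """A random admissible duplex and a matching synthetic target window.

    Used for property tests: builds helices of length >= 2 separated by
    random gaps, then synthesises a window sequence that pairs accordingly
    (Watson-Crick away from the first eight pairs, occasionally G:U).
    Returns (structure, window).
    """
    m = len(mirna)
    pairs = []
    i = int(rng.integers(1, max(2, m // 3)))
    while i <= m - 1:
        helix = int(rng.integers(2, 5))
        helix = min(helix, m - i + 1)
        if helix < 2:
            break
        for k in range(helix):
            pairs.append(i + k)
        i += helix
        i += int(rng.integers(1, max_gap))
        if rng.random() < 0.4:
            break
    if len(pairs) < 2:
        pairs = [1, 2]
    # target gaps between helices
    t_gaps = []
    for a, b in zip(pairs, pairs[1:]):
        if b == a + 1:
            t_gaps.append(0)
        else:
            t_gaps.append(int(rng.integers(0, max_gap)))
    # lay out target coordinates from the 3'-most pair backwards
    window_len = m + sum(t_gaps) + 10
    t = window_len - 3
    t_pos = [t]
    for k, (a, b) in enumerate(zip(pairs, pairs[1:])):
        stacked = (b == a + 1) and (t_gaps[k] == 0)
        t -= 1 + t_gaps[k]
        if not stacked and b == a + 1 and t_gaps[k] == 0:
            t -= 1
        t_pos.append(t)
    window = [BASES[int(k)] for k in rng.integers(0, 4, window_len)]
    gu_count = 0
    plist = []
    for ordinal, (mi_pos, tp) in enumerate(zip(pairs, t_pos), start=1):
        base = mirna[mi_pos - 1]
        partner = COMPLEMENT[base]
        if ordinal > 8 and gu_count < 4 and base in "GU" and rng.random() < 0.15:
            partner = "U" if base == "G" else "G"
            gu_count += 1
        window[tp - 1] = partner
        plist.append((mi_pos, tp))
    win = RnaSequence("window", "".join(window))
    structure = DuplexStructure.from_pairs(plist, mirna, win, params)
    return structure, win
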