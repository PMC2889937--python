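"""Candidate-zone discovery on the per-anchor attraction profile.

For each (microRNA, UTR) pair an attraction profile records the minimum
anchored duplex energy at every UTR position (0.0 where no admissible
structure anchors).  After 3-nt sliding-window smoothing, candidate zones are
the maximal runs of positions whose smoothed energy falls below ``x_ratio``
of the perfect-complement energy; each zone must contain a representative
duplex below the stricter ``y_ratio`` cut-off whose pairing starts at
microRNA position 1 or 2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .energy import (
    AnchoredOptimum,
    DuplexStructure,
    EnergyParameters,
    anchor_energy_profile,
    anchored_minimum,
)
from .sequences import RnaSequence

#: numerical slack for energy threshold comparisons (kcal/mol)
ENERGY_EPS = 1e-9


@dataclass(frozen=True)
class ZoneThresholds:
    """Energy-ratio cut-offs relative to the perfect-complement energy.

    A ratio of 0.25 means the duplex has 25% of the energy of a perfect
    reverse-complementary hybrid; ``x_ratio`` gates the smoothed profile,
    ``y_ratio`` gates the representative duplex.
    """

    x_ratio: float = 0.24
    y_ratio: float = 0.25

    def __post_init__(self):
        if not 0 < self.x_ratio <= self.y_ratio < 1:
            raise ValueError("thresholds must satisfy 0 < x_ratio <= y_ratio < 1")


@dataclass
class AttractionProfile:
    """Raw and smoothed per-position anchored energies for one (miRNA, UTR)."""

    utr_id: str
    mirna_id: str
    raw_energy: np.ndarray
    smoothed_energy: np.ndarray
    #: auxiliary per-anchor data used when selecting zone representatives
    seed_ok: np.ndarray = field(default=None, repr=False)
    e_12: np.ndarray = field(default=None, repr=False)


@dataclass
class CandidateZone:
    """A UTR interval with its representative duplex (the unit of prediction)."""

    utr_id: str
    mirna_id: str
    start: int
    end: int
    representative: DuplexStructure
    representative_anchor: int
    score: float | None = None


def smooth_profile(raw: np.ndarray) -> np.ndarray:
    """Mean over a centred window of 3, truncated at the sequence ends."""
    raw = np.asarray(raw, dtype=float)
    csum = np.concatenate(([0.0], np.cumsum(raw)))
    n = raw.size
    lo = np.maximum(np.arange(n) - 1, 0)
    hi = np.minimum(np.arange(n) + 1, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def prune_anchor_group(candidates_at_anchor: list[DuplexStructure],
                       mirna: RnaSequence | None = None) -> list[DuplexStructure]:
    """Seed-preference pruning among structures sharing one anchor.

    If any structure carries a perfect 5'-end pairing of >= 7 consecutive
    nucleotides starting at microRNA position 1, all seedless structures at
    that anchor are discarded; otherwise the list is returned unchanged.
    """
    if any(s.has_seed_region() for s in candidates_at_anchor):
        return [s for s in candidates_at_anchor if s.has_seed_region()]
    return list(candidates_at_anchor)


def build_profile(mirna: RnaSequence, utr: RnaSequence,
                  params: EnergyParameters) -> AttractionProfile:
    """Per-position attraction profile after seed-preference pruning.

    raw_energy[p] is the energy of the pruned anchored optimum at p (the best
    seed-region structure where one exists, otherwise the overall optimum);
    0.0 where no admissible structure anchors.
    """
    prof = anchor_energy_profile(mirna, utr, params)
    raw = np.where(prof["seed_ok"], prof["e_seed"], prof["e_all"])
    raw = np.where(np.isinf(raw), 0.0, raw)
    return AttractionProfile(
        utr_id=utr.id,
        mirna_id=mirna.id,
        raw_energy=raw,
        smoothed_energy=smooth_profile(raw),
        seed_ok=prof["seed_ok"],
        e_12=prof["e_12"],
    )


def _representative_for(profile: AttractionProfile, run: range,
                        mirna: RnaSequence, utr: RnaSequence,
                        params: EnergyParameters, y_cut: float,
                        anchored: list[AnchoredOptimum] | None):
    """Minimum-energy eligible representative within a sub-threshold run.

    Eligible anchors carry a pruned optimum with raw energy <= y_cut whose
    5'-most pairing uses microRNA position 1 or 2.
    """
    raw = profile.raw_energy
    candidates = [p for p in run if raw[p] <= y_cut + ENERGY_EPS and raw[p] < 0.0]
    # cheap screen: a non-seed optimum can only start at position 1/2 if the
    # position-restricted minimum coincides with the overall minimum
    if profile.e_12 is not None and anchored is None:
        candidates = [
            p for p in candidates
            if profile.seed_ok[p] or abs(profile.e_12[p] - raw[p]) < ENERGY_EPS
        ]
    best = None
    for p in sorted(candidates, key=lambda p: (raw[p], p)):
        if anchored is not None:
            # caller supplies per-anchor (already pruned) optima
            opt = anchored[p]
        else:
            opt = anchored_minimum(
                mirna, utr, p + 1, params, require_seed=bool(profile.seed_ok[p])
            )
        if opt.structure is None:
            continue
        if opt.structure.pairs[0][0] not in (1, 2):
            continue
        if opt.structure.energy > y_cut + ENERGY_EPS:
            continue
        if best is None or opt.structure.energy < best.structure.energy:
            best = opt
        break  # candidates are sorted by raw energy: first admissible is minimal
    return best


def call_zones(profile: AttractionProfile, anchored: list[AnchoredOptimum] | None,
               e_perfect: float, thresholds: ZoneThresholds, *,
               mirna: RnaSequence | None = None, utr: RnaSequence | None = None,
               params: EnergyParameters | None = None) -> list[CandidateZone]:
    """Call candidate zones from the smoothed profile.

    Zones are maximal runs with smoothed energy <= x_ratio * e_perfect that
    contain an eligible representative (raw energy <= y_ratio * e_perfect,
    pairing starting at microRNA position 1 or 2).  The zone interval is the
    run extended to cover the representative's target footprint.  ``anchored``
    may pre-supply per-position optima; otherwise they are computed on demand
    from (mirna, utr, params).
    """
    if e_perfect >= 0:
        raise ValueError("e_perfect must be negative")
    if anchored is None and (mirna is None or utr is None or params is None):
        raise ValueError("pass either anchored optima or (mirna, utr, params)")
    x_cut = thresholds.x_ratio * e_perfect
    y_cut = thresholds.y_ratio * e_perfect
    sm = profile.smoothed_energy
    below = sm <= x_cut + ENERGY_EPS
    zones: list[CandidateZone] = []
    n = sm.size
    p = 0
    while p < n:
        if not below[p]:
            p += 1
            continue
        q = p
        while q + 1 < n and below[q + 1]:
            q += 1
        rep = _representative_for(
            profile, range(p, q + 1), mirna, utr, params, y_cut, anchored
        )
        if rep is not None:
            t_lo, t_hi = rep.structure.target_footprint
            zones.append(CandidateZone(
                utr_id=profile.utr_id,
                mirna_id=profile.mirna_id,
                start=min(p + 1, t_lo),
                end=max(q + 1, t_hi),
                representative=rep.structure,
                representative_anchor=rep.anchor,
            ))
        p = q + 1
    return zones


def merge_zones(zones: list[CandidateZone]) -> list[CandidateZone]:
    """Union overlapping zone intervals; the highest-scoring constituent's
    representative (and score) represents the merged zone."""
    if not zones:
        return []
    keys = {(z.utr_id, z.mirna_id) for z in zones}
    if len(keys) > 1:
        raise ValueError("zones to merge must share (utr_id, mirna_id)")
    if any(z.score is None for z in zones):
        raise ValueError("zones must be scored before merging")
    ordered = sorted(zones, key=lambda z: (z.start, z.end, -z.score))
    merged: list[CandidateZone] = []
    for z in ordered:
        cur = replace(z)
        if merged and cur.start <= merged[-1].end:
            prev = merged[-1]
            best = prev if prev.score >= cur.score else cur
            merged[-1] = replace(
                best,
                start=min(prev.start, cur.start),
                end=max(prev.end, cur.end),
            )
        else:
            merged.append(cur)
    return merged
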