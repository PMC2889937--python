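"""End-to-end target-site prediction and evaluation.

For every (microRNA, UTR) pair the pipeline builds the attraction profile,
calls candidate zones, extracts the model features for each zone's
representative, scores zones with the boosted committee, merges overlapping
zones and emits ranked prediction records.  Post-filters derive the three
prediction classes: no-seed (all records), seed (perfect 7-mer seed match in
the site), and conserved seed (6-mer match at microRNA positions 2-7
perfectly conserved across the aligned species with an additional reference
match to base 1 or 8).  Stringency tiers (sens / spec) come from the model's
calibrated score thresholds.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .boosting import BoostedModel
from .energy import (
    EnergyParameters,
    load_default_parameters,
    perfect_complement_energy,
)
from .features import DEFAULT_MODEL_FEATURES, extract_features
from .selection import LabeledTable
from .sequences import COMPLEMENT, RnaSequence, reverse_complement
from .zones import CandidateZone, ZoneThresholds, build_profile, call_zones, merge_zones

logger = logging.getLogger("mirspot")


@dataclass(frozen=True)
class PredictionRecord:
    """A merged, ranked target-site call with class and stringency flags."""

    utr_id: str
    mirna_id: str
    start: int
    end: int
    score: float
    seed_flag: bool
    conserved_flag: bool
    stringency: str  # "spec", "sens" or "below"

    @property
    def class_flags(self) -> dict:
        return {
            "no_seed": True,
            "seed": self.seed_flag,
            "conserved_seed": self.conserved_flag,
        }


@dataclass(frozen=True)
class ValidatedSite:
    """An experimentally supported binding interval on a transcript's UTR."""

    transcript_id: str
    start: int  # 1-based inclusive
    end: int
    mirna_family: tuple

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}-{self.end}")


@dataclass
class AlignedUtrSet:
    """Per-species aligned UTR rows (equal length, '-' gaps)."""

    transcript_id: str
    rows: dict  # species id -> aligned string over {A,C,G,U,-}
    reference: str

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment for {self.transcript_id}")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least two species")
        if self.reference not in self.rows:
            raise ValueError(f"reference species {self.reference!r} missing")

    def reference_sequence(self) -> str:
        return self.rows[self.reference].replace("-", "")

    def column_of(self, ref_pos: int) -> int:
        """Alignment column (1-based) of a 1-based reference position."""
        count = 0
        for col, ch in enumerate(self.rows[self.reference], start=1):
            if ch != "-":
                count += 1
                if count == ref_pos:
                    return col
        raise IndexError(f"reference position {ref_pos} beyond alignment")


@dataclass
class PredictConfig:
    """Run-time configuration for the prediction pipeline."""

    thresholds: ZoneThresholds = field(default_factory=ZoneThresholds)
    params: EnergyParameters | None = None
    require_class: str = "no_seed"  # no_seed | seed | conserved_seed
    stringency: str = "all"  # all | sens | spec

    def __post_init__(self):
        if self.params is None:
            self.params = load_default_parameters()


def seed_match(site_sequence: str, mirna: RnaSequence) -> bool:
    """True iff the site contains a perfect Watson-Crick reverse complement
    of microRNA positions 1-7 or 2-8 (no G:U)."""
    site = site_sequence.upper().replace("T", "U")
    for lo, hi in ((0, 7), (1, 8)):
        probe = reverse_complement(mirna.residues[lo:hi])
        if probe in site:
            return True
    return False


def conserved_seed_match(alignment: AlignedUtrSet, record: PredictionRecord,
                         mirna: RnaSequence) -> bool:
    """Conserved-seed post-filter.

    Requires a Watson-Crick 6-mer match to microRNA positions 2-7 inside the
    record interval whose alignment columns are gap-free and identical across
    all species, with the reference additionally matching microRNA base 1 or
    base 8 adjacent to the 6-mer.
    """
    ref = alignment.reference_sequence()
    if record.end > len(ref):
        logger.warning(
            "record %s:%d-%d extends beyond reference row of %s; "
            "treating as unmappable",
            record.utr_id, record.start, record.end, alignment.transcript_id)
        return False
    probe = reverse_complement(mirna.residues[1:7])  # positions 2-7
    segment = ref[record.start - 1:record.end]
    rows = list(alignment.rows.values())
    for off in range(len(segment) - 5):
        q = record.start + off  # 1-based ref position of the 6-mer start
        if segment[off:off + 6] != probe:
            continue
        # base 1 pairs 3' of the 6-mer on the target; base 8 pairs 5' of it
        extra = False
        if q + 6 <= len(ref) and ref[q + 5] == COMPLEMENT[mirna[0]]:
            extra = True
        if q - 2 >= 0 and q - 1 >= 1 and ref[q - 2] == COMPLEMENT[mirna[7]]:
            extra = True
        if not extra:
            continue
        try:
            cols = [alignment.column_of(q + k) for k in range(6)]
        except IndexError:
            continue
        conserved = all(
            row[c - 1] == probe[k] and row[c - 1] != "-"
            for k, c in enumerate(cols)
            for row in rows
        )
        if conserved:
            return True
    return False


def _stringency(score: float, thresholds: dict | None) -> str:
    if thresholds is None:
        return "below"
    if score >= thresholds["spec"]:
        return "spec"
    if score >= thresholds["sens"]:
        return "sens"
    return "below"


def candidate_zones_for(mirna: RnaSequence, utr: RnaSequence,
                        config: PredictConfig) -> list:
    """Profile -> zone calling for one (microRNA, UTR) pair."""
    e_perfect = perfect_complement_energy(mirna, config.params)
    profile = build_profile(mirna, utr, config.params)
    return call_zones(
        profile, None, e_perfect, config.thresholds,
        mirna=mirna, utr=utr, params=config.params,
    )


def predict(mirnas: list, utrs: list, model: BoostedModel,
            config: PredictConfig | None = None,
            alignments: dict | None = None) -> list:
    """Rank candidate target sites for every (microRNA, UTR) combination.

    ``alignments`` optionally maps UTR ids to AlignedUtrSet for the
    conserved-seed flag.  Records are sorted by descending score and filtered
    by the configured class and stringency.
    """
    config = config or PredictConfig()
    if not mirnas or not utrs:
        logger.warning("empty input: %d microRNAs, %d UTRs", len(mirnas), len(utrs))
        return []
    records: list = []
    for utr in utrs:
        for mirna in mirnas:
            zones = candidate_zones_for(mirna, utr, config)
            for z in zones:
                feats = extract_features(z, utr, mirna, model.feature_set)
                z.score = model.score(feats)
            merged = merge_zones(zones) if zones else []
            for z in merged:
                site_seq = utr.residues[z.start - 1:z.end]
                s_flag = seed_match(site_seq, mirna)
                c_flag = False
                if s_flag and alignments and utr.id in alignments:
                    probe_record = PredictionRecord(
                        utr_id=utr.id, mirna_id=mirna.id, start=z.start,
                        end=z.end, score=z.score, seed_flag=True,
                        conserved_flag=False, stringency="below")
                    c_flag = conserved_seed_match(
                        alignments[utr.id], probe_record, mirna)
                records.append(PredictionRecord(
                    utr_id=utr.id,
                    mirna_id=mirna.id,
                    start=z.start,
                    end=z.end,
                    score=round(float(z.score), 12),
                    seed_flag=s_flag,
                    conserved_flag=c_flag,
                    stringency=_stringency(z.score, model.thresholds),
                ))
    records.sort(key=lambda r: (-r.score, r.utr_id, r.mirna_id, r.start))
    return filter_records(records, config.require_class, config.stringency)


def filter_records(records: list, require_class: str = "no_seed",
                   stringency: str = "all") -> list:
    """Apply class and stringency post-filters to prediction records."""
    if require_class not in ("no_seed", "seed", "conserved_seed"):
        raise ValueError(f"unknown prediction class {require_class!r}")
    if stringency not in ("all", "sens", "spec"):
        raise ValueError(f"unknown stringency {stringency!r}")
    out = []
    for r in records:
        if require_class == "seed" and not r.seed_flag:
            continue
        if require_class == "conserved_seed" and not r.conserved_flag:
            continue
        if stringency == "spec" and r.stringency != "spec":
            continue
        if stringency == "sens" and r.stringency not in ("sens", "spec"):
            continue
        out.append(r)
    return out


def _overlaps(z: CandidateZone, site: ValidatedSite) -> bool:
    return z.start <= site.end and site.start <= z.end


def build_training_set(candidates: dict, validated: list, utrs: dict,
                       mirnas: dict, feature_set: tuple = DEFAULT_MODEL_FEATURES,
                       full_catalogue: bool = False) -> LabeledTable:
    """Labeled instances from candidate zones and validated binding sites.

    ``candidates`` maps (transcript_id, mirna_id) -> list of CandidateZone.
    Per validated site, the energetically most favorable candidate of the
    site's microRNA family overlapping the interval becomes the positive
    instance; the most favorable non-overlapping candidate of the same
    interaction becomes the negative instance.
    """
    from .features import CATALOGUE

    names = CATALOGUE if full_catalogue else feature_set
    rows = []
    labels = []
    for site in validated:
        pool = []
        for mid in site.mirna_family:
            pool.extend(
                (z, mid) for z in candidates.get((site.transcript_id, mid), [])
            )
        if not pool:
            logger.info("no candidates for %s / %s; site skipped",
                        site.transcript_id, ",".join(site.mirna_family))
            continue
        overlapping = [(z, mid) for z, mid in pool if _overlaps(z, site)]
        outside = [(z, mid) for z, mid in pool if not _overlaps(z, site)]
        for group, label in ((overlapping, 1), (outside, 0)):
            if not group:
                continue
            z, mid = min(group, key=lambda t: (t[0].representative.energy,
                                               t[0].start, t[1]))
            utr = utrs[site.transcript_id]
            rows.append(extract_features(z, utr, mirnas[mid], names))
            labels.append(label)
    if not rows:
        raise ValueError("no training instances could be built")
    frame = pd.DataFrame(rows, columns=list(names))
    return LabeledTable(frame, np.asarray(labels))


def psilac_accuracy(predictions: list, fold_changes: pd.DataFrame,
                    cutoff: float = -0.1) -> float:
    """Fraction of measured predicted interactions with log2 fold change
    below ``cutoff`` (positive predictive value on proteomic data).

    ``fold_changes`` has columns (gene, mirna, log2fc); predictions without a
    measurement are excluded from both counts.
    """
    measured = {
        (str(g), str(m)): float(v)
        for g, m, v in fold_changes[["gene", "mirna", "log2fc"]].itertuples(index=False)
    }
    interactions = {(r.utr_id, r.mirna_id) for r in predictions}
    values = [measured[key] for key in interactions if key in measured]
    if not values:
        logger.warning("no predicted interaction has a fold-change measurement")
        return math.nan
    return float(np.mean([v < cutoff for v in values]))
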