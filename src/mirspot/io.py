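"""Readers and writers for the standard formats the tool touches.

FASTA (sequences, alignments) goes through Biopython; BED and TSV tables go
through pandas.  Coordinates are 1-based inclusive internally, BED is 0-based
half-open, GFF3 is 1-based inclusive.  Transcripts, not chromosomes, are the
coordinate system.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .pipeline import AlignedUtrSet, PredictionRecord, ValidatedSite
from .sequences import RnaSequence, SequenceError

logger = logging.getLogger("mirspot")

PREDICTION_COLUMNS = (
    "utr_id", "mirna_id", "start", "end", "score",
    "seed_flag", "conserved_flag", "stringency",
)


class ParseError(ValueError):
    """Raised for malformed input files."""


def read_fasta(path) -> list:
    """Read a multiple-FASTA file into validated RnaSequence records.

    Record ids are the first whitespace-delimited header token; duplicate ids
    are rejected; T is normalised to U.
    """
    records: list = []
    seen: set = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises bare ValueError on bad records
        raise ParseError(f"{path}: {exc}") from exc
    for rec in parsed:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(RnaSequence(rec.id, str(rec.seq)))
        except SequenceError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: list, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, len(rec.residues), width):
                fh.write(rec.residues[k:k + width] + "\n")


def read_aligned_fasta(path, reference: str) -> AlignedUtrSet:
    """Read one per-transcript multi-species alignment (aligned FASTA).

    Row ids are ``species`` or ``species|transcript``; rows must share one
    length over the alphabet {A, C, G, U, -}.
    """
    rows: dict = {}
    transcript = None
    for rec in SeqIO.parse(str(path), "fasta"):
        species, _, tid = rec.id.partition("|")
        if tid:
            transcript = tid
        seq = str(rec.seq).upper().replace("T", "U")
        bad = set(seq) - set("ACGU-")
        if bad:
            raise ParseError(f"{path}: row {rec.id!r} has invalid characters {sorted(bad)}")
        rows[species] = seq
    if not rows:
        raise ParseError(f"{path}: empty alignment")
    lengths = {len(r) for r in rows.values()}
    if len(lengths) > 1:
        raise ParseError(f"{path}: ragged alignment (row lengths {sorted(lengths)})")
    if reference not in rows:
        raise ParseError(f"{path}: reference species {reference!r} not present "
                         f"(rows: {sorted(rows)})")
    return AlignedUtrSet(
        transcript_id=transcript or reference, rows=rows, reference=reference
    )


def write_aligned_fasta(alignment: AlignedUtrSet, path) -> None:
    with open(path, "w") as fh:
        for species, row in alignment.rows.items():
            fh.write(f">{species}|{alignment.transcript_id}\n{row}\n")


def read_bed_sites(path, families: dict | None = None) -> list:
    """Read validated binding intervals from BED (0-based half-open).

    The BED name column holds a microRNA id or family id; ``families``
    optionally maps family ids to microRNA id lists.
    """
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6), dtype={"chrom": str, "name": str},
    )
    sites = []
    for row in frame.itertuples(index=False):
        family = tuple(families.get(row.name, [row.name])) if families else (row.name,)
        sites.append(ValidatedSite(
            transcript_id=row.chrom,
            start=int(row.start) + 1,
            end=int(row.end),
            mirna_family=family,
        ))
    return sites


def write_bed_intervals(rows: list, path) -> None:
    """Write (chrom, start_1based, end, name, score, strand) rows as BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score}\t{strand}\n")


def read_families_tsv(path) -> dict:
    """family id -> list of microRNA ids, from a two-column TSV."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["family", "mirna"],
                        dtype=str, comment="#")
    out: dict = {}
    for row in frame.itertuples(index=False):
        out.setdefault(row.family, []).append(row.mirna)
    return out


def write_predictions(records: list, path, fmt: str = "tsv") -> None:
    """Write prediction records as TSV, BED or GFF3."""
    fmt = fmt.lower()
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
            for r in records:
                fh.write(
                    f"{r.utr_id}\t{r.mirna_id}\t{r.start}\t{r.end}\t"
                    f"{r.score:.6f}\t{int(r.seed_flag)}\t{int(r.conserved_flag)}\t"
                    f"{r.stringency}\n"
                )
    elif fmt == "bed":
        with open(path, "w") as fh:
            for r in records:
                fh.write(
                    f"{r.utr_id}\t{r.start - 1}\t{r.end}\t{r.mirna_id}\t"
                    f"{r.score:.6f}\t+\n"
                )
    elif fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in records:
                attrs = (
                    f"ID={r.utr_id}:{r.mirna_id}:{r.start};mirna={r.mirna_id};"
                    f"seed={int(r.seed_flag)};conserved={int(r.conserved_flag)};"
                    f"stringency={r.stringency}"
                )
                fh.write(
                    f"{r.utr_id}\tmirspot\tmiRNA_target_site\t{r.start}\t{r.end}\t"
                    f"{r.score:.6f}\t+\t.\t{attrs}\n"
                )
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def read_predictions_tsv(path) -> list:
    frame = pd.read_csv(path, sep="\t", dtype={"utr_id": str, "mirna_id": str})
    return [
        PredictionRecord(
            utr_id=row.utr_id, mirna_id=row.mirna_id, start=int(row.start),
            end=int(row.end), score=float(row.score),
            seed_flag=bool(row.seed_flag), conserved_flag=bool(row.conserved_flag),
            stringency=str(row.stringency),
        )
        for row in frame.itertuples(index=False)
    ]


def write_feature_table(table, path) -> None:
    """Tab-separated feature table with a label column."""
    frame = table.frame.copy()
    frame.insert(0, "label", table.labels)
    frame.to_csv(path, sep="\t", index=False)


def read_feature_table(path):
    from .selection import LabeledTable

    frame = pd.read_csv(path, sep="\t")
    if "label" not in frame.columns:
        raise ParseError(f"{path}: feature table lacks a 'label' column")
    labels = frame.pop("label").to_numpy()
    return LabeledTable(frame, labels)


def read_psilac_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "mirna": str})
    missing = {"gene", "mirna", "log2fc"} - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return frame
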