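"""RNA sequence primitives shared across the package.

Sequences are stored 5'->3' over the alphabet {A, C, G, U}.  DNA-style input
(T, lowercase) is normalised on construction; anything else is rejected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGU"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

#: Watson-Crick plus G:U wobble pairing, keyed (strand1 base, strand2 base).
CAN_PAIR = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class RnaSequence:
    """A named RNA sequence, 5'->3'."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        seq = self.residues.upper().replace("T", "U")
        if not seq:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(seq) - set(BASES)
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos) -> str:
        return self.residues[pos]

    def codes(self) -> np.ndarray:
        """Integer encoding (A=0, C=1, G=2, U=3) as a uint8 array."""
        return np.frombuffer(
            self.residues.translate(_CODE_TABLE).encode("ascii"), dtype=np.uint8
        ).copy()

    def reverse_complement(self, new_id: str | None = None) -> "RnaSequence":
        rc = "".join(COMPLEMENT[b] for b in reversed(self.residues))
        return RnaSequence(new_id or f"{self.id}|rc", rc)


_CODE_TABLE = str.maketrans({b: chr(i) for b, i in BASE_CODE.items()})


def complement(base: str) -> str:
    return COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper().replace("T", "U")))


def can_pair(a: str, b: str) -> bool:
    return (a, b) in CAN_PAIR


def is_gu(a: str, b: str) -> bool:
    return (a, b) in {("G", "U"), ("U", "G")}
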