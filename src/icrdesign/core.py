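"""Core sequence types shared across the package.

Coordinates are 0-based, half-open everywhere (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

_VALID = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""

    def __init__(self, seq_id: str, position: int, char: str):
        self.seq_id = seq_id
        self.position = position
        self.char = char
        super().__init__(
            f"sequence {seq_id!r}: invalid character {char!r} at position {position} "
            "(allowed: A, C, G, T, N)"
        )


def validate_dna(seq: str, seq_id: str = "<anonymous>") -> None:
    """Reject any character outside the uppercase {A,C,G,T,N} alphabet,
    naming the first offending position."""
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise SequenceAlphabetError(seq_id, i, ch)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicSequence:
    """A named DNA string over {A,C,G,T,N}, optionally carrying the genomic
    window it was extracted from as ``source = (contig, start)``.

    Invariants: uppercase alphabet only, length >= 1.
    """

    id: str
    seq: str
    source: Optional[Tuple[str, int]] = None

    def __post_init__(self):
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        validate_dna(self.seq, self.id)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, new_id: Optional[str] = None) -> "GenomicSequence":
        return GenomicSequence(new_id or f"{self.id}_rc", reverse_complement(self.seq))

    @classmethod
    def from_raw(cls, id: str, seq: str, source=None) -> "GenomicSequence":
        """Build from possibly lower-case text, uppercasing first."""
        return cls(id, seq.upper(), source)


def as_text(seq) -> str:
    """Accept either a GenomicSequence or a plain string."""
    if isinstance(seq, GenomicSequence):
        return seq.seq
    if isinstance(seq, str):
        return seq
    raise TypeError(f"expected GenomicSequence or str, got {type(seq).__name__}")


def cpg_positions(seq) -> list[int]:
    """All 0-based start offsets p with seq[p:p+2] == "CG".

    Ns never participate in a CpG. Invalid characters are rejected with the
    offending position named.
    """
    text = as_text(seq)
    if isinstance(seq, str):
        validate_dna(text)
    if not text:
        raise ValueError("cpg_positions: empty sequence")
    positions = []
    start = text.find("CG")
    while start != -1:
        positions.append(start)
        start = text.find("CG", start + 1)
    return positions


@dataclass(frozen=True)
class CpGGrid:
    """Ordered CpG dinucleotide start positions of a sequence.

    Consecutive positions always differ by >= 2 (CG cannot overlap CG).
    """

    positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        pos = self.positions
        if list(pos) != sorted(set(pos)):
            raise ValueError("CpGGrid positions must be strictly increasing")
        for a, b in zip(pos, pos[1:]):
            if b - a < 2:
                raise ValueError(f"CpG positions {a} and {b} overlap")

    @classmethod
    def from_sequence(cls, seq) -> "CpGGrid":
        return cls(tuple(cpg_positions(seq)))

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self):
        return iter(self.positions)

    def spacings(self) -> list[int]:
        """Gaps between consecutive CpG start positions."""
        p = self.positions
        return [b - a for a, b in zip(p, p[1:])]

    def verify(self, seq) -> None:
        """Check completeness and correctness against a sequence."""
        expected = tuple(cpg_positions(seq))
        if expected != self.positions:
            raise ValueError(
                f"CpGGrid does not match sequence: grid has {len(self.positions)} "
                f"positions, sequence has {len(expected)} CG dinucleotides"
            )
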