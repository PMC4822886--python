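"""Shared DNA primitives: alphabet checks, strands, reverse complement.

These are deliberately tiny and dependency-free; both the keyboard codec and
the strand composer build on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidSequenceError

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA_SET = frozenset(DNA_ALPHABET)

FORWARD = "forward"
REVERSE = "reverse"


def check_dna(sequence: str, *, what: str = "sequence") -> str:
    """Return ``sequence`` unchanged, or raise if it is not plain DNA."""
    if not isinstance(sequence, str):
        raise InvalidSequenceError(f"{what} must be a string, got {type(sequence).__name__}")
    bad = set(sequence) - _DNA_SET
    if bad:
        raise InvalidSequenceError(
            f"{what} contains non-DNA characters: {sorted(bad)!r}"
        )
    return sequence


def reverse_complement(dna: str) -> str:
    """Watson–Crick reverse complement (an involution on valid DNA)."""
    check_dna(dna, what="reverse_complement input")
    return dna.translate(_COMPLEMENT)[::-1]


def max_homopolymer_run(dna: str) -> int:
    """Length of the longest run of one base; 0 for the empty string.

    Long homopolymers degrade both synthesis and Sanger base calling, which
    is why the keyboard design bounds them.
    """
    check_dna(dna, what="max_homopolymer_run input")
    best = run = 0
    prev = ""
    for base in dna:
        run = run + 1 if base == prev else 1
        prev = base
        if run > best:
            best = run
    return best


@dataclass(frozen=True)
class Strand:
    """An identified DNA molecule.

    ``orientation`` records how the information-bearing layout sits on the
    stored sequence: ``"forward"`` means the layout reads as given,
    ``"reverse"`` means the stored sequence is the reverse complement of the
    layout (the camouflage flip applied to even-numbered strands).
    """

    id: str
    sequence: str
    orientation: str = FORWARD
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        check_dna(self.sequence, what=f"strand {self.id!r}")
        if self.orientation not in (FORWARD, REVERSE):
            raise InvalidSequenceError(
                f"orientation must be {FORWARD!r} or {REVERSE!r}, got {self.orientation!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complemented(self) -> "Strand":
        flipped = REVERSE if self.orientation == FORWARD else FORWARD
        return Strand(self.id, reverse_complement(self.sequence), flipped, self.description)
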