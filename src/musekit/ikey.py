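"""iKey-64: a keyboard-shaped substitution cipher for writing text in DNA.

The cipher maps each of 64 keyboard buttons to one of the 4^3 = 64 DNA
codons.  Codons fall into three structural categories:

* CAT1 — all three bases distinct (24 codons).  Assigned to the most
  frequently used buttons (all digits, both word spacers, and the most
  common letters), so frequent characters never contribute more than a
  single repeated base at a codon junction.
* CAT2 — first and third base equal, middle different (12 codons).
  Assigned to mid-frequency letters.
* CAT3 — at least one adjacent repeated base (28 codons).  Assigned to the
  rarest characters and to function keys; the four fully homopolymeric
  codons AAA/CCC/GGG/TTT are reserved for function keys.

With that allocation, ordinary text never produces a homopolymer run longer
than 4 bases and digit strings never exceed 2 — the property that keeps
multiplexed Sanger traces in register.

The reference keyboard shipped here reproduces every printed constraint of
the original 212-nt DNA keyboard record (pBZ38): button order equals the
record's codon order, '1'=AGC, '0'=CTG, 'v'=GTT, 'k'=TTC, space1=AGT,
space2=CTA, and AAA/CCC/GGG/TTT on function keys.  The remaining
letter-to-codon assignments follow descending English letter frequency; the
full layout is a documented reconstruction (the figure showing the physical
keyboard does not print it), and every operation takes the keyboard as data
so alternative layouts need no code changes.
"""

from __future__ import annotations

import math
import random
import string
from dataclasses import dataclass
from enum import Enum
from functools import cached_property, lru_cache
from itertools import product
from typing import Iterable, Sequence

from .dna import Strand, check_dna, max_homopolymer_run  # noqa: F401  (re-export)
from .errors import (
    DecodingError,
    EncodingError,
    InvalidCodonError,
    MalformedMessageError,
    MalformedRecordError,
    ValidationError,
)

DNA_BASES = "ACGT"
ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in product(DNA_BASES, repeat=3))

HOMOPOLYMERIC_CODONS = ("AAA", "CCC", "GGG", "TTT")

#: Function-button labels recognised by the codec.  ``forward``/``reverse``
#: are carried as ordinary function buttons; decoding them does not flip any
#: strand.
FUNCTION_LABELS = ("start", "end", "shift", "space1", "space2", "forward", "reverse")


class CodonCategory(Enum):
    CAT1 = 1  # three distinct bases
    CAT2 = 2  # first == third, middle different
    CAT3 = 3  # contains an adjacent repeat


class ButtonKind(Enum):
    CHARACTER = "character"
    DIGIT = "digit"
    FUNCTION = "function"


def _check_codon(codon: str) -> str:
    if not isinstance(codon, str) or len(codon) != 3:
        raise InvalidCodonError(f"codon must be a length-3 string, got {codon!r}")
    check_dna(codon, what=f"codon {codon!r}")
    return codon


def classify_codon(codon: str) -> CodonCategory:
    """Structural category of a codon (see module docstring)."""
    a, b, c = _check_codon(codon)
    if a == b or b == c:
        return CodonCategory.CAT3
    if a == c:
        return CodonCategory.CAT2
    return CodonCategory.CAT1


def category_census() -> tuple[int, int, int]:
    """Counts of (CAT1, CAT2, CAT3) over all 64 codons — (24, 12, 28)."""
    counts = {cat: 0 for cat in CodonCategory}
    for codon in ALL_CODONS:
        counts[classify_codon(codon)] += 1
    return (counts[CodonCategory.CAT1], counts[CodonCategory.CAT2], counts[CodonCategory.CAT3])


def variant_count(category_sizes: Iterable[int] | int) -> int:
    """Number of keyboards reachable by shuffling codons within categories.

    The product of factorials of the category sizes, computed exactly with
    arbitrary-precision integers: (24, 12, 28) gives ~9.1e61 variants, a
    single category of 64 gives 64! ~ 1.3e89.
    """
    if isinstance(category_sizes, int):
        category_sizes = (category_sizes,)
    result = 1
    for size in category_sizes:
        if size < 0:
            raise ValueError(f"category sizes must be nonnegative, got {size}")
        result *= math.factorial(size)
    return result


@dataclass(frozen=True)
class Button:
    """One keyboard button: a label bound to a codon."""

    label: str
    codon: str
    kind: ButtonKind

    def __post_init__(self) -> None:
        _check_codon(self.codon)
        if not self.label:
            raise ValidationError("button label must be non-empty")

    @property
    def category(self) -> CodonCategory:
        return classify_codon(self.codon)


@dataclass(frozen=True)
class IKey:
    """An ordered 64-button keyboard; button position defines record order."""

    buttons: tuple[Button, ...]

    def __post_init__(self) -> None:
        if len(self.buttons) != 64:
            raise ValidationError(f"an iKey needs exactly 64 buttons, got {len(self.buttons)}")
        codons = [b.codon for b in self.buttons]
        if len(set(codons)) != 64:
            dupes = sorted({c for c in codons if codons.count(c) > 1})
            raise ValidationError(f"codons must be a bijection onto the codon space; duplicates: {dupes}")
        labels = [b.label.casefold() for b in self.buttons]
        if len(set(labels)) != 64:
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"button labels must be distinct; duplicates: {dupes}")

    @cached_property
    def _by_codon(self) -> dict[str, Button]:
        return {b.codon: b for b in self.buttons}

    @cached_property
    def _by_label(self) -> dict[str, Button]:
        return {b.label.casefold(): b for b in self.buttons}

    def button_for_codon(self, codon: str) -> Button:
        try:
            return self._by_codon[codon]
        except KeyError:
            raise DecodingError(f"codon {codon!r} is not on this keyboard") from None

    def button_for_label(self, label: str) -> Button:
        try:
            return self._by_label[label.casefold()]
        except KeyError:
            raise EncodingError(f"no button labelled {label!r} on this keyboard") from None

    def codon_of(self, label: str) -> str:
        return self.button_for_label(label).codon

    def category_census(self) -> tuple[int, int, int]:
        counts = {cat: 0 for cat in CodonCategory}
        for b in self.buttons:
            counts[b.category] += 1
        return (counts[CodonCategory.CAT1], counts[CodonCategory.CAT2], counts[CodonCategory.CAT3])


@dataclass(frozen=True)
class EncodedText:
    """A DNA-encoded character sequence; ``frame`` marks start/end codons."""

    dna: str
    frame: bool = False

    def __post_init__(self) -> None:
        check_dna(self.dna, what="encoded text")
        if len(self.dna) % 3:
            raise ValidationError(f"encoded text length must be divisible by 3, got {len(self.dna)}")

    def __str__(self) -> str:
        return self.dna

    def __len__(self) -> int:
        return len(self.dna)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_chars(
    text: str,
    ikey: IKey,
    shift_policy: bool = True,
    space_button: str = "space1",
) -> EncodedText:
    """Encode characters as a codon concatenation, without framing codons.

    With ``shift_policy`` on, an uppercase letter is emitted as the shift
    codon followed by the base letter's codon; off, case is folded away.
    ``space_button`` selects which spacer codon writes the word separator
    (strand parity chooses between space1/space2 downstream).
    """
    if space_button not in ("space1", "space2"):
        raise EncodingError(f"space_button must be 'space1' or 'space2', got {space_button!r}")
    space_codon = ikey.codon_of(space_button)
    parts: list[str] = []
    for pos, ch in enumerate(text):
        if ch == " ":
            parts.append(space_codon)
            continue
        if ch in string.ascii_uppercase:
            if shift_policy:
                parts.append(ikey.codon_of("shift"))
            ch = ch.lower()
        try:
            button = ikey.button_for_label(ch)
        except EncodingError:
            raise EncodingError(f"character {ch!r} at position {pos} has no button") from None
        if button.kind is ButtonKind.FUNCTION:
            raise EncodingError(f"character {ch!r} at position {pos} collides with a function label")
        parts.append(button.codon)
    return EncodedText("".join(parts), frame=False)


def encode_message(
    text: str,
    ikey: IKey,
    shift_policy: bool = True,
    space_button: str = "space1",
) -> EncodedText:
    """Encode a message with start/end framing codons."""
    body = encode_chars(text, ikey, shift_policy=shift_policy, space_button=space_button)
    return EncodedText(ikey.codon_of("start") + body.dna + ikey.codon_of("end"), frame=True)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

class IKeyDecoder:
    """Incremental codon-stream decoder with shift handling.

    Used by both the plain string decoder and the chromatogram-pattern
    walker, which feeds codons from homogeneous trace blocks and explicit
    separators for spacer troughs.
    """

    def __init__(self, ikey: IKey):
        self._ikey = ikey
        self._parts: list[str] = []
        self._pending_shift = False
        self._shift_offset = -1

    def feed_codon(self, codon: str, offset: int = -1) -> None:
        button = self._ikey.button_for_codon(codon)
        label = button.label
        if label == "shift":
            if self._pending_shift:
                raise MalformedMessageError(f"two consecutive shift codons at offset {offset}")
            self._pending_shift = True
            self._shift_offset = offset
            return
        if label in ("space1", "space2"):
            if self._pending_shift:
                raise MalformedMessageError(f"shift codon before a spacer at offset {offset}")
            self._parts.append(" ")
            return
        if button.kind is ButtonKind.FUNCTION:
            if self._pending_shift:
                raise MalformedMessageError(f"shift codon before function {label!r} at offset {offset}")
            self._parts.append(f"<{label}>")
            return
        ch = button.label
        if self._pending_shift:
            ch = ch.upper()
            self._pending_shift = False
        self._parts.append(ch)

    def feed_separator(self, token: str = " ") -> None:
        if self._pending_shift:
            raise MalformedMessageError("shift codon immediately before a word separator")
        self._parts.append(token)

    def finish(self) -> str:
        if self._pending_shift:
            raise MalformedMessageError(
                f"trailing shift codon with no successor (offset {self._shift_offset})"
            )
        return "".join(self._parts)


def _as_dna(dna: EncodedText | str) -> str:
    return dna.dna if isinstance(dna, EncodedText) else dna


def decode_dna(dna: EncodedText | str, ikey: IKey) -> str:
    """Inverse of :func:`encode_chars`; both spacers decode to a space."""
    seq = _as_dna(dna)
    check_dna(seq, what="decode input")
    if len(seq) % 3:
        raise DecodingError(f"DNA length {len(seq)} is not divisible by 3")
    decoder = IKeyDecoder(ikey)
    for offset in range(0, len(seq), 3):
        decoder.feed_codon(seq[offset : offset + 3], offset)
    return decoder.finish()


def decode_message(dna: EncodedText | str, ikey: IKey) -> str:
    """Inverse of :func:`encode_message`: strips and checks the framing codons."""
    seq = _as_dna(dna)
    if len(seq) % 3:
        raise DecodingError(f"DNA length {len(seq)} is not divisible by 3")
    if len(seq) < 6:
        raise MalformedMessageError("a framed message needs at least start and end codons")
    if seq[:3] != ikey.codon_of("start"):
        raise MalformedMessageError(f"message does not begin with the start codon ({seq[:3]})")
    if seq[-3:] != ikey.codon_of("end"):
        raise MalformedMessageError(f"message does not finish with the end codon ({seq[-3:]})")
    return decode_dna(seq[3:-3], ikey)


# ---------------------------------------------------------------------------
# DNA-record serialization
# ---------------------------------------------------------------------------

RECORD_FLANK = "T" * 10
RECORD_LENGTH = 10 + 64 * 3 + 10  # 212


def serialize_ikey(ikey: IKey) -> Strand:
    """Write the keyboard onto DNA: 64 codons in button order, 10-T flanks."""
    interior = "".join(b.codon for b in ikey.buttons)
    return Strand("iKey-64", RECORD_FLANK + interior + RECORD_FLANK)


def parse_ikey_record(record: Strand | str, labels: Sequence[str]) -> IKey:
    """Recover a keyboard from its DNA record and an ordered label list.

    Button kinds are inferred from the labels: single digits are digit
    buttons, other single characters are character buttons, multi-character
    labels are function buttons.
    """
    seq = record.sequence if isinstance(record, Strand) else record
    check_dna(seq, what="iKey record")
    if len(seq) != RECORD_LENGTH:
        raise MalformedRecordError(f"iKey record must be {RECORD_LENGTH} nt, got {len(seq)}")
    if seq[:10] != RECORD_FLANK or seq[-10:] != RECORD_FLANK:
        raise MalformedRecordError("iKey record must be flanked by 10 T nucleotides on each side")
    interior = seq[10:-10]
    if len(labels) != 64:
        raise MalformedRecordError(f"need 64 button labels, got {len(labels)}")
    buttons = []
    for i, label in enumerate(labels):
        codon = interior[3 * i : 3 * i + 3]
        if len(label) == 1 and label in string.digits:
            kind = ButtonKind.DIGIT
        elif len(label) == 1:
            kind = ButtonKind.CHARACTER
        else:
            kind = ButtonKind.FUNCTION
        buttons.append(Button(label, codon, kind))
    return IKey(tuple(buttons))


# ---------------------------------------------------------------------------
# The reference keyboard (reconstruction; see module docstring)
# ---------------------------------------------------------------------------

#: Interior of the printed 212-nt keyboard record (pBZ38) between its 10-T
#: flanks: 64 pairwise-distinct codons in button order.
PBZ38_INTERIOR = (
    "CGGAGCTGAGACCGAACGTAGGCTTCGGCACTGTTAGAAGATATCAACAATTCACGTATGCGCGTGGTAACT"
    "TGTCTTTTGATTCACTGCCATTCTGCGGAGCTCCCATTCAGATCCACCTGGAGGGGAAAGATAGTTTATGTC"
    "ACACAGTACTAACAAAAACCCGGGTTTAGTCTAGGCGGTCCTGCCCCG"
)

#: English letter frequencies (percent, Concise Oxford Dictionary ordering);
#: ties keep table row order.
LETTER_FREQUENCY_PERCENT = {
    "e": 11.16, "a": 8.50, "r": 7.58, "i": 7.54, "o": 7.16, "t": 6.95,
    "n": 6.65, "s": 5.74, "l": 5.49, "c": 4.54, "u": 3.63, "d": 3.38,
    "p": 3.17, "m": 3.01, "h": 3.00, "g": 2.47, "b": 2.07, "f": 1.81,
    "y": 1.78, "w": 1.29, "k": 1.10, "v": 1.01, "x": 0.29, "z": 0.27,
    "j": 0.20, "q": 0.20,
}

#: 21 punctuation characters filling the leftover CAT3 buttons.
REFERENCE_PUNCTUATION = ".,:;!?'\"-&()/@#$%+=*_"

_PINNED_CODONS = {
    "GTT": ("v", ButtonKind.CHARACTER),
    "TTC": ("k", ButtonKind.CHARACTER),
    "AGT": ("space1", ButtonKind.FUNCTION),
    "CTA": ("space2", ButtonKind.FUNCTION),
    "AAA": ("start", ButtonKind.FUNCTION),
    "CCC": ("shift", ButtonKind.FUNCTION),
    "GGG": ("end", ButtonKind.FUNCTION),
    "TTT": ("forward", ButtonKind.FUNCTION),
}


@lru_cache(maxsize=1)
def build_reference_ikey() -> IKey:
    """Construct the shipped reference keyboard.

    Deterministic reconstruction: button order follows the printed DNA
    record; digits 1–9,0 sit at buttons 2–11 (matching '1'=AGC and '0'=CTG);
    pinned codons hold; remaining letters fill CAT1 then CAT2 codons in
    descending frequency order; 'reverse' and punctuation fill the leftover
    CAT3 codons in record order.
    """
    codons = [PBZ38_INTERIOR[i : i + 3] for i in range(0, 192, 3)]
    assignment: dict[int, tuple[str, ButtonKind]] = {}
    for i, digit in enumerate("1234567890"):
        if classify_codon(codons[1 + i]) is not CodonCategory.CAT1:
            raise ValidationError("digit buttons must carry three-distinct-base codons")
        assignment[1 + i] = (digit, ButtonKind.DIGIT)
    for codon, (label, kind) in _PINNED_CODONS.items():
        assignment[codons.index(codon)] = (label, kind)

    frequency_order = sorted(
        LETTER_FREQUENCY_PERCENT,
        key=lambda ch: -LETTER_FREQUENCY_PERCENT[ch],
    )
    letters = [ch for ch in frequency_order if ch not in ("v", "k")]
    cat1_letters = letters[:12]
    cat2_letters = letters[12:]
    cat3_labels = ["reverse"] + list(REFERENCE_PUNCTUATION)

    queues = {
        CodonCategory.CAT1: [(ch, ButtonKind.CHARACTER) for ch in cat1_letters],
        CodonCategory.CAT2: [(ch, ButtonKind.CHARACTER) for ch in cat2_letters],
        CodonCategory.CAT3: [
            (label, ButtonKind.FUNCTION if label == "reverse" else ButtonKind.CHARACTER)
            for label in cat3_labels
        ],
    }
    buttons = []
    for i, codon in enumerate(codons):
        if i in assignment:
            label, kind = assignment[i]
        else:
            label, kind = queues[classify_codon(codon)].pop(0)
        buttons.append(Button(label, codon, kind))
    if any(queues.values()):
        raise ValidationError("reference layout did not exhaust its label queues")
    return IKey(tuple(buttons))


def randomize_ikey(base: IKey, seed: int) -> IKey:
    """Permute codons independently within each category (seeded).

    Labels, kinds, and per-button categories are unchanged, so the census
    stays (24, 12, 28) and any of the 24!·12!·28! variants is reachable.
    """
    if not isinstance(base, IKey):
        raise ValidationError(f"base must be an IKey, got {type(base).__name__}")
    rng = random.Random(seed)
    new_codons: dict[int, str] = {}
    for cat in CodonCategory:
        indices = [i for i, b in enumerate(base.buttons) if b.category is cat]
        codons = [base.buttons[i].codon for i in indices]
        rng.shuffle(codons)
        new_codons.update(zip(indices, codons))
    buttons = tuple(
        Button(b.label, new_codons[i], b.kind) for i, b in enumerate(base.buttons)
    )
    return IKey(buttons)
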