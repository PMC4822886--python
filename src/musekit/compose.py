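"""MuSE composition: fragmenting a communication across DNA strands.

A communication carries a desired message *m*, a decoy *d*, a keyboard *k*,
per-strand watermarks, and a combination key.  The message is split into
word groups shared between consecutive strand pairs (n1+n2, n3+n4, ...),
the decoy between the circularly shifted pairs (n2+n3, ..., nN+n1).  Pair
partners encode identical codons inside words but use different spacer
codons (space1 on odd strands, space2 on even strands), so co-sequencing a
correct pair shows large homogeneous peaks inside words and 3-nt
heterogeneous troughs at word boundaries.  Even-numbered strands are
emitted as the reverse complement of their information layout — the
camouflage flip that defeats naive co-sequencing with generic primers.

Strand layout (information orientation, all regions length-aligned across
strands):

    [ExternalFw site][leading filler][Primer_Key site][watermark codon]
    [combination key][Primer_Message site][message slot][decoy slot]
    [trailing filler][rc(ExternalRv site)]

Filler regions are seeded-random DNA with a bounded homopolymer run; the
``camouflage`` filler policy deliberately injects long C/A homopolymer
stretches so that co-sequencing from the external primers loses register.
"""

from __future__ import annotations

import math
import random
import re
from dataclasses import dataclass, field

from .dna import (  # noqa: F401  (Strand/reverse_complement re-exported here)
    FORWARD,
    REVERSE,
    Strand,
    check_dna,
    reverse_complement,
)
from .errors import (
    ExtractionError,
    FragmentationError,
    KeySpecError,
    ValidationError,
)
from .ikey import IKey, build_reference_ikey, encode_message

# Primer sequences used in the original constructs; the same sequences ship
# as packaged fixtures (musekit.io).
PRIMER_KEY_SEQ = "TAATACGACTCACTATAGGG"
PRIMER_MESSAGE_SEQ = "GCTAGTTATTGCTCAGCGG"
PRIMER_EXTERNAL_FW_SEQ = "GACATTAACCTATAAAAATAGGC"
PRIMER_EXTERNAL_RV_SEQ = "GCATCTTCCAGGAAATCTC"

#: Watermark codons: permutations of AGC ordered so odd strands carry
#: AGC/GAC/ACG, the pattern observed in the printed n1/n3/n5 constructs.
WATERMARK_CODONS = ("AGC", "GCA", "GAC", "CAG", "ACG", "CGA")

MAX_STRANDS = len(WATERMARK_CODONS)

# The recreated WWII communication used throughout demos and tests.
WWII_MESSAGE = "Bletchley Park: GC&CS Codebreakers"
WWII_DECOY = "Captain Ridley's Shooting Party"
WWII_COMBINATION_KEY = "Pascal's triangle: d2r6-reverse"


# ---------------------------------------------------------------------------
# Combination keys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairingPlan:
    """Ordered strand pairs resolved from a combination key."""

    pairs: tuple[tuple[str, str], ...]
    role: str = "message"
    direction: str = "reverse"

    def strand_ids(self) -> tuple[str, ...]:
        return tuple(sid for pair in self.pairs for sid in pair)


_KEY_RE = re.compile(
    r"^(?:pascal:|pascal'?s\s+triangle:?\s*)d(?P<diag>\d+)r(?P<row>\d+)-(?P<direction>forward|reverse)$"
)


def resolve_combination_key(spec: str, strand_count: int) -> PairingPlan:
    """Resolve a Pascal's-triangle combination key into a pairing plan.

    ``"pascal:d2r6-reverse"`` (or the spelled-out riddle text) enumerates
    diagonal 2 of Pascal's triangle down to row 6 — the counting numbers
    1..6 — maps the entries to strand indices, and pairs consecutive
    entries: (n1, n2), (n3, n4), (n5, n6).
    """
    norm = spec.strip().lower().replace("’", "'")
    m = _KEY_RE.match(norm)
    if not m:
        raise KeySpecError(f"cannot parse combination key {spec!r}")
    diag = int(m.group("diag"))
    row = int(m.group("row"))
    if diag < 1 or row < diag - 1:
        raise KeySpecError(f"invalid diagonal/row in {spec!r}")
    entries = [math.comb(r, diag - 1) for r in range(diag - 1, row + 1)]
    if len(entries) != strand_count:
        raise KeySpecError(
            f"key {spec!r} yields {len(entries)} entries but the communication has "
            f"{strand_count} strands"
        )
    if sorted(entries) != list(range(1, strand_count + 1)):
        raise KeySpecError(f"key {spec!r} does not enumerate strand indices 1..{strand_count}")
    pairs = tuple(
        (f"n{entries[i]}", f"n{entries[i + 1]}") for i in range(0, strand_count, 2)
    )
    return PairingPlan(pairs=pairs, role="message", direction=m.group("direction"))


def circular_shift(plan: PairingPlan) -> PairingPlan:
    """Circularly permute the flattened strand ordering by one.

    Applied to the message plan this yields the decoy plan:
    (n1,n2),(n3,n4),(n5,n6) -> (n2,n3),(n4,n5),(n6,n1).
    """
    ids = plan.strand_ids()
    shifted = ids[1:] + ids[:1]
    pairs = tuple((shifted[i], shifted[i + 1]) for i in range(0, len(shifted), 2))
    role = "decoy" if plan.role == "message" else "message"
    return PairingPlan(pairs=pairs, role=role, direction=plan.direction)


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def fragment_message(text: str, n_pairs: int) -> list[str]:
    """Split a text on word boundaries into ``n_pairs`` contiguous fragments.

    Word counts are near-equal with earlier fragments taking the remainder;
    joining the fragments with single spaces restores the word sequence.
    """
    if n_pairs < 1:
        raise FragmentationError(f"n_pairs must be >= 1, got {n_pairs}")
    words = text.split()
    if not words:
        raise FragmentationError("cannot fragment an empty text")
    if len(words) < n_pairs:
        raise FragmentationError(
            f"text has {len(words)} words but {n_pairs} fragments were requested"
        )
    q, r = divmod(len(words), n_pairs)
    sizes = [q + 1] * r + [q] * (n_pairs - r)
    fragments = []
    pos = 0
    for size in sizes:
        fragments.append(" ".join(words[pos : pos + size]))
        pos += size
    return fragments


# ---------------------------------------------------------------------------
# Communications
# ---------------------------------------------------------------------------

@dataclass
class Communication:
    """A full MuSE communication: message, decoy, keyboard, key, watermarks."""

    message: str
    decoy: str
    ikey: IKey = field(default_factory=build_reference_ikey)
    strand_count: int = 6
    combination_key: str = ""
    watermarks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = self.strand_count
        if n < 2 or n % 2:
            raise ValidationError(f"strand_count must be even and >= 2, got {n}")
        if n > MAX_STRANDS:
            raise ValidationError(
                f"at most {MAX_STRANDS} strands are supported (distinct watermark codons)"
            )
        if not self.combination_key:
            self.combination_key = f"Pascal's triangle: d2r{n}-reverse"
        if not self.watermarks:
            self.watermarks = WATERMARK_CODONS[:n]
        if len(self.watermarks) != n:
            raise ValidationError(f"need {n} watermarks, got {len(self.watermarks)}")
        # Fail fast on anything that cannot be encoded or resolved.
        resolve_combination_key(self.combination_key, n)
        encode_message(self.message, self.ikey)
        encode_message(self.decoy, self.ikey)
        fragment_message(self.message, n // 2)
        fragment_message(self.decoy, n // 2)

    @property
    def n_pairs(self) -> int:
        return self.strand_count // 2

    def message_plan(self) -> PairingPlan:
        return resolve_combination_key(self.combination_key, self.strand_count)

    def decoy_plan(self) -> PairingPlan:
        return circular_shift(self.message_plan())


# ---------------------------------------------------------------------------
# Filler DNA
# ---------------------------------------------------------------------------

def random_dna(rng: random.Random, length: int, max_run: int = 2) -> str:
    """Seeded random DNA whose homopolymer runs never exceed ``max_run``."""
    if length < 0:
        raise ValidationError(f"filler length must be nonnegative, got {length}")
    out: list[str] = []
    run = 0
    for _ in range(length):
        choices = "ACGT" if (run < max_run or not out) else "ACGT".replace(out[-1], "")
        base = rng.choice(choices)
        run = run + 1 if out and base == out[-1] else 1
        out.append(base)
    return "".join(out)


def _filler(rng: random.Random, length: int, policy: str, strand_index: int) -> str:
    """Per-strand variable DNA; the camouflage policy injects a long C/A run."""
    if policy == "plain":
        return random_dna(rng, length)
    if policy == "camouflage":
        run_base = "C" if strand_index % 2 else "A"
        run = run_base * 6
        if length <= len(run):
            return run[:length]
        body = random_dna(rng, length - len(run))
        mid = (length - len(run)) // 2
        return body[:mid] + run + body[mid:]
    raise ValidationError(f"unknown filler policy {policy!r}")


# ---------------------------------------------------------------------------
# Strand construction and deconstruction
# ---------------------------------------------------------------------------

LEAD_FILLER_LENGTH = 60
TAIL_FILLER_LENGTH = 45


def _decoy_fragment_index(strand_index: int, n: int) -> int:
    """0-based decoy-fragment index carried by 1-based strand ``strand_index``.

    The decoy pairing is the circular shift (n2,n3), (n4,n5), ..., (nN,n1).
    """
    if strand_index % 2 == 0:
        return strand_index // 2 - 1
    return n // 2 - 1 if strand_index == 1 else (strand_index - 1) // 2 - 1


def _pad(encoded: str, target: int, rng: random.Random) -> str:
    return encoded + random_dna(rng, target - len(encoded))


def build_strands(
    comm: Communication,
    filler_seed: int = 0,
    filler_policy: str = "plain",
) -> list[Strand]:
    """Build the N strands of a communication (deterministic for a seed).

    Every region has the same length on every strand, so any template mix
    stays base-aligned along the whole read — the property chromatogram
    patterning depends on.
    """
    n = comm.strand_count
    msg_frags = fragment_message(comm.message, comm.n_pairs)
    decoy_frags = fragment_message(comm.decoy, comm.n_pairs)

    def slot_len(frags: list[str]) -> int:
        return max(
            len(encode_message(f, comm.ikey, space_button="space1")) for f in frags
        )

    msg_slot = slot_len(msg_frags)
    decoy_slot = slot_len(decoy_frags)

    strands = []
    for i in range(1, n + 1):
        rng = random.Random(f"musekit:{filler_seed}:{i}")
        space = "space1" if i % 2 else "space2"
        msg = encode_message(msg_frags[(i - 1) // 2], comm.ikey, space_button=space)
        dec = encode_message(
            decoy_frags[_decoy_fragment_index(i, n)], comm.ikey, space_button=space
        )
        layout = "".join(
            [
                PRIMER_EXTERNAL_FW_SEQ,
                _filler(rng, LEAD_FILLER_LENGTH, filler_policy, i),
                PRIMER_KEY_SEQ,
                comm.watermarks[i - 1],
                encode_message(comm.combination_key, comm.ikey, space_button=space).dna,
                PRIMER_MESSAGE_SEQ,
                _pad(msg.dna, msg_slot, rng),
                _pad(dec.dna, decoy_slot, rng),
                # Trailing filler stays homopolymer-free regardless of policy:
                # the camouflage stretches sit upstream only, so message-side
                # reads keep register.
                _filler(rng, TAIL_FILLER_LENGTH, "plain", i),
                reverse_complement(PRIMER_EXTERNAL_RV_SEQ),
            ]
        )
        if i % 2:
            strands.append(Strand(f"n{i}", layout, FORWARD))
        else:
            strands.append(Strand(f"n{i}", reverse_complement(layout), REVERSE))
    return strands


def orient_to_primer(strand: Strand, primer_seq: str) -> str:
    """Return the read a primer would produce: bases 3' of its unique site."""
    hits = []
    for oriented in (strand.sequence, reverse_complement(strand.sequence)):
        start = oriented.find(primer_seq)
        while start != -1:
            hits.append(oriented[start + len(primer_seq) :])
            start = oriented.find(primer_seq, start + 1)
    if not hits:
        raise ExtractionError(f"primer has no site in strand {strand.id!r}")
    if len(hits) > 1:
        raise ExtractionError(f"primer site is ambiguous in strand {strand.id!r}")
    return hits[0]


def _extract_pair_texts(read_a: str, read_b: str, ikey: IKey) -> list[str]:
    """Decode every start..end framed region shared by two aligned reads."""
    from .pattern import decode_framed_regions  # local import avoids a cycle

    length = min(len(read_a), len(read_b))
    mask = [read_a[i] == read_b[i] for i in range(length)]
    frames = decode_framed_regions(read_a[:length], mask, ikey)
    return [frame.text for frame in frames]


def extract_communication(
    strands: list[Strand],
    ikey: IKey,
    plan: PairingPlan,
    primer_seq: str = PRIMER_MESSAGE_SEQ,
) -> tuple[str, str]:
    """Recover the texts revealed by a pairing plan and by its circular shift.

    Element 0 is the text shared by the given plan's pairs, element 1 the
    text shared by the circularly shifted pairs.  For the message plan that
    is ``(message, decoy)``; handing in the shifted plan returns the decoy
    first.  With only two strands both framed regions sit on the same pair
    and the slot order (message before decoy) disambiguates.
    """
    by_id = {s.id: s for s in strands}

    def text_under(p: PairingPlan) -> str:
        fragments = []
        for a_id, b_id in p.pairs:
            try:
                a, b = by_id[a_id], by_id[b_id]
            except KeyError as exc:
                raise ExtractionError(f"plan references unknown strand {exc.args[0]!r}") from None
            texts = _extract_pair_texts(
                orient_to_primer(a, primer_seq), orient_to_primer(b, primer_seq), ikey
            )
            if not texts:
                raise ExtractionError(f"no shared framed region in pair {a_id}+{b_id}")
            fragments.append(texts[0] if p.role == "message" else texts[-1])
        return " ".join(fragments)

    return text_under(plan), text_under(circular_shift(plan))
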