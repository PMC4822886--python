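"""Chromatogram-pattern detection and decoding.

A multiplexed trace of a correct strand pair alternates large homogeneous
blocks (shared message codons) with 3-nt heterogeneous troughs (the
space1/space2 spacer codons that differ between pair partners).  The
decoder finds maximal same-class blocks, locates start..end framed codon
runs inside homogeneous spans (searching all three frame offsets), emits a
word separator for each codon-aligned 3-nt trough, and decodes the words
with the keyboard.  A trough whose channels show more than two distinct
bases per column cannot be a pair spacer (three or more templates disagree
there) and is emitted as a watermark placeholder instead of a space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .dna import Strand, check_dna, reverse_complement
from .errors import AnchoringError, MusekitError, ValidationError
from .ikey import IKey, IKeyDecoder
from .cosequence import (
    HETEROGENEOUS,
    HOMOGENEOUS,
    PrimerSpec,
    TemplateMix,
    Trace,
    simulate_cosequencing,
)

#: Homogeneous runs shorter than this many positions (3 codons) are treated
#: as chance matches inside variable regions and merged into neighbours.
DEFAULT_MIN_BLOCK = 9

WATERMARK_TOKEN = "<wm>"


@dataclass(frozen=True)
class Block:
    """A maximal same-class span, 0-based half-open trace coordinates."""

    start: int
    end: int
    klass: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"empty block [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DecodedFrame:
    """One start..end framed region and its decoded text."""

    start: int
    end: int
    text: str


@dataclass
class PatternReport:
    """Decoder output: block structure, framed regions, words, contrast."""

    blocks: list[Block]
    message_frames: list[DecodedFrame]
    decoded_words: list[str]
    contrast: float | None


def _runs(klasses: Sequence[str]) -> list[Block]:
    blocks: list[Block] = []
    start = 0
    for i in range(1, len(klasses) + 1):
        if i == len(klasses) or klasses[i] != klasses[start]:
            blocks.append(Block(start, i, klasses[start]))
            start = i
    return blocks


def _merge_short_homogeneous(blocks: list[Block], min_block: int) -> list[Block]:
    """Demote short homogeneous runs (chance matches) and re-merge."""
    if len(blocks) <= 1:
        return blocks
    relabelled = [
        Block(b.start, b.end, HETEROGENEOUS)
        if b.klass == HOMOGENEOUS and len(b) < min_block
        else b
        for b in blocks
    ]
    merged: list[Block] = []
    for b in relabelled:
        if merged and merged[-1].klass == b.klass:
            merged[-1] = Block(merged[-1].start, b.end, b.klass)
        else:
            merged.append(b)
    return merged


def detect_blocks(trace: Trace, min_block: int = DEFAULT_MIN_BLOCK) -> list[Block]:
    """Maximal same-class blocks of a trace.

    Homogeneous runs shorter than ``min_block`` are merged into their
    neighbours; a single-run trace is returned as-is.
    """
    if not trace.positions:
        raise ValidationError("cannot detect blocks in an empty trace")
    if min_block < 1:
        raise ValidationError(f"min_block must be >= 1, got {min_block}")
    return _merge_short_homogeneous(_runs(trace.klasses), min_block)


# ---------------------------------------------------------------------------
# Framed decoding (shared between trace space and sequence space)
# ---------------------------------------------------------------------------

def decode_framed_regions(
    calls: str,
    homogeneous: Sequence[bool],
    ikey: IKey,
    gap_token: Callable[[int], str] | None = None,
) -> list[DecodedFrame]:
    """Decode every start..end framed codon run in a classified call string.

    ``homogeneous[i]`` says whether position ``i`` carries a reliable shared
    base.  The codon frame is found by scanning every offset for a fully
    homogeneous start codon; inside a frame, a codon containing any
    non-homogeneous position is a single-codon gap — a word separator (or
    the ``gap_token`` result) — and two consecutive gap codons end the
    attempt, so only regions bounded by decodable blocks survive.
    """
    start_codon = ikey.codon_of("start")
    end_codon = ikey.codon_of("end")
    length = min(len(calls), len(homogeneous))
    frames: list[DecodedFrame] = []
    p = 0
    while p + 3 <= length:
        if not (all(homogeneous[p : p + 3]) and calls[p : p + 3] == start_codon):
            p += 1
            continue
        frame = _walk_frame(calls, homogeneous, ikey, p, start_codon, end_codon, gap_token)
        if frame is not None:
            frames.append(frame)
            p = frame.end
        else:
            p += 1
    return frames


def _walk_frame(
    calls: str,
    homogeneous: Sequence[bool],
    ikey: IKey,
    start: int,
    start_codon: str,
    end_codon: str,
    gap_token: Callable[[int], str] | None,
) -> DecodedFrame | None:
    length = min(len(calls), len(homogeneous))
    decoder = IKeyDecoder(ikey)
    q = start + 3
    previous_was_gap = False
    while q + 3 <= length:
        codon_homogeneous = all(homogeneous[q : q + 3])
        if codon_homogeneous:
            codon = calls[q : q + 3]
            if codon == end_codon:
                try:
                    return DecodedFrame(start, q + 3, decoder.finish())
                except MusekitError:
                    return None
            try:
                decoder.feed_codon(codon, q)
            except MusekitError:
                return None
            previous_was_gap = False
        else:
            if previous_was_gap:
                return None
            token = gap_token(q) if gap_token is not None else " "
            try:
                decoder.feed_separator(token)
            except MusekitError:
                return None
            previous_was_gap = True
        q += 3
    return None


def _trace_gap_token(trace: Trace) -> Callable[[int], str]:
    def token(q: int) -> str:
        for pos in trace.positions[q : q + 3]:
            distinct = sum(1 for v in pos.intensities.values() if v > 0)
            if distinct > 2:
                return WATERMARK_TOKEN
        return " "

    return token


def decode_pattern(
    trace: Trace,
    ikey: IKey,
    min_block: int = DEFAULT_MIN_BLOCK,
    contrast_stat: str = "mean",
) -> PatternReport:
    """Detect patterning in a trace and decode the embedded message.

    Returns an empty-word report (never raises) when no decodable framed
    region exists.  ``contrast`` summarises the minor-peak fraction over
    heterogeneous positions (mean, or median via ``contrast_stat``).
    """
    blocks = detect_blocks(trace, min_block)
    homogeneous = [k == HOMOGENEOUS for k in trace.klasses]
    frames = decode_framed_regions(trace.calls, homogeneous, ikey, _trace_gap_token(trace))
    words = [w for f in frames for w in f.text.split()]
    minors = [
        1.0 - max(p.intensities.values()) / total
        for p in trace.positions
        if p.klass == HETEROGENEOUS and (total := sum(p.intensities.values())) > 0
    ]
    if not minors:
        contrast = None
    elif contrast_stat == "mean":
        contrast = sum(minors) / len(minors)
    elif contrast_stat == "median":
        contrast = sorted(minors)[len(minors) // 2]
    else:
        raise ValidationError(f"unknown contrast statistic {contrast_stat!r}")
    return PatternReport(blocks=blocks, message_frames=frames, decoded_words=words, contrast=contrast)


# ---------------------------------------------------------------------------
# Sequence-space oracle
# ---------------------------------------------------------------------------

def _anchor_read(strand: Strand, anchor: str) -> str:
    hits = []
    for oriented in (strand.sequence, reverse_complement(strand.sequence)):
        start = oriented.find(anchor)
        while start != -1:
            hits.append(oriented[start + len(anchor) :])
            start = oriented.find(anchor, start + 1)
    if not hits:
        raise AnchoringError(f"anchor absent from strand {strand.id!r}")
    if len(hits) > 1:
        raise AnchoringError(f"anchor ambiguous in strand {strand.id!r}")
    return hits[0]


def compare_sequences(
    a: Strand,
    b: Strand,
    anchor: str,
    min_block: int = 1,
) -> list[Block]:
    """Positionwise match/mismatch blocks of two strands co-aligned 3' of a
    unique anchor — the brute-force oracle for noiseless trace detection.

    Coordinates match a trace primed with the anchor.  ``min_block`` applies
    the same short-homogeneous-run merging as :func:`detect_blocks`.
    """
    check_dna(anchor, what="anchor")
    if not anchor:
        raise AnchoringError("anchor must be non-empty")
    read_a = _anchor_read(a, anchor)
    read_b = _anchor_read(b, anchor)
    length = min(len(read_a), len(read_b))
    if length == 0:
        raise AnchoringError("anchor sits at the very end of a strand; nothing to compare")
    klasses = [
        HOMOGENEOUS if read_a[i] == read_b[i] else HETEROGENEOUS for i in range(length)
    ]
    return _merge_short_homogeneous(_runs(klasses), min_block)


# ---------------------------------------------------------------------------
# Contrast tuning
# ---------------------------------------------------------------------------

def contrast_curve(
    mix_ratios: Sequence[float],
    pair: tuple[Strand, Strand],
    primer: PrimerSpec,
    read_length: int = 700,
) -> list[tuple[float, float]]:
    """Mean minor-peak fraction at template-mismatch positions per ratio.

    Under linear mixing the minor fraction is min(r, 1-r): maximal contrast
    at 0.5, vanishing as one partner dominates (where the consensus aligns
    perfectly with the dominant strand).
    """
    a, b = pair
    curve = []
    for ratio in mix_ratios:
        if not 0.0 <= ratio <= 1.0:
            raise ValueError(f"ratio must be within [0, 1], got {ratio}")
        mix = TemplateMix([(a, ratio), (b, 1.0 - ratio)]) if 0 < ratio < 1 else (
            TemplateMix([(a, 1.0)]) if ratio == 1 else TemplateMix([(b, 1.0)])
        )
        trace = simulate_cosequencing(mix, primer, read_length=read_length)
        minors = []
        for pos in trace.positions:
            positive = [v for v in pos.intensities.values() if v > 0]
            if len(positive) > 1:
                minors.append(1.0 - max(positive) / sum(positive))
        curve.append((ratio, sum(minors) / len(minors) if minors else 0.0))
    return curve


def plot_trace(trace: Trace, path: str | None = None, max_positions: int = 250):
    """Render a pseudo-chromatogram (stacked channel intensities).

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = min(len(trace.positions), max_positions)
    xs = range(1, n + 1)
    fig, ax = plt.subplots(figsize=(max(6, n / 12), 3))
    colours = {"A": "#2ca02c", "C": "#1f77b4", "G": "#333333", "T": "#d62728"}
    for base in "ACGT":
        ax.plot(xs, [trace.positions[i].intensities[base] for i in range(n)],
                label=base, color=colours[base], linewidth=0.9)
    for i in range(n):
        if trace.positions[i].klass != HOMOGENEOUS:
            ax.axvspan(i + 0.5, i + 1.5, color="#f5d0d0", alpha=0.4, linewidth=0)
    ax.set_xlabel("read position")
    ax.set_ylabel("channel intensity")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper right", ncol=4, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
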