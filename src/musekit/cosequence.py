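"""In-silico multiplexed Sanger co-sequencing.

A template mixture is "sequenced" with a common primer: every template in
which the primer anneals contributes its (normalized) concentration to the
channel of its base at each read position.  Positions where all
participating templates agree show one full-height channel (a large
homogeneous peak); positions where they differ split the signal (small
heterogeneous peaks).  The model is noiseless by default — the patterning
claims it supports are structural, not quantitative — with optional seeded
Gaussian channel noise.

An optional dephasing policy models the register loss seen when long
homopolymers sit in non-identical regions: once templates disagree inside a
window that contains a long run in any participating template, every
downstream position becomes unreliable and is called N.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .dna import Strand, check_dna, max_homopolymer_run, reverse_complement
from .errors import AmbiguousPrimerError, NoSignalError, ValidationError

BASES = "ACGT"

HOMOGENEOUS = "homogeneous"
HETEROGENEOUS = "heterogeneous"
UNRELIABLE = "unreliable"

DEFAULT_READ_LENGTH = 700  # typical usable Sanger read
DEFAULT_PURITY = 0.9  # top-channel share required to call a peak homogeneous


@dataclass(frozen=True)
class PrimerSpec:
    """A named sequencing primer; Sanger-realistic primers are >= 15 nt."""

    name: str
    sequence: str
    allow_short: bool = False

    def __post_init__(self) -> None:
        check_dna(self.sequence, what=f"primer {self.name!r}")
        if len(self.sequence) < 15 and not self.allow_short:
            raise ValidationError(
                f"primer {self.name!r} is {len(self.sequence)} nt; "
                "Sanger primers should be >= 15 nt (set allow_short to override)"
            )


@dataclass(frozen=True)
class AnnealSite:
    """Where a primer anneals: extension proceeds 3' of ``offset`` on the
    stated orientation of the template."""

    strand_id: str
    offset: int  # 0-based position just past the primer's 3' end
    template_orientation: str  # "as-given" or "reverse-complement"


AS_GIVEN = "as-given"
REVCOMP = "reverse-complement"


def find_anneal_sites(primer: PrimerSpec, strand: Strand) -> list[AnnealSite]:
    """Exact full-length matches of the primer on either template orientation."""
    sites = []
    for orientation, seq in (
        (AS_GIVEN, strand.sequence),
        (REVCOMP, reverse_complement(strand.sequence)),
    ):
        start = seq.find(primer.sequence)
        while start != -1:
            sites.append(AnnealSite(strand.id, start + len(primer.sequence), orientation))
            start = seq.find(primer.sequence, start + 1)
    return sites


@dataclass
class TemplateMix:
    """Templates with relative concentrations, normalized to sum 1."""

    entries: list[tuple[Strand, float]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("a template mix needs at least one entry")
        total = 0.0
        for strand, conc in self.entries:
            if conc < 0:
                raise ValidationError(f"concentration of {strand.id!r} is negative")
            total += conc
        if total <= 0:
            raise ValidationError("total concentration must be positive")
        self.entries = [(s, c / total) for s, c in self.entries]


@dataclass(frozen=True)
class DephasingPolicy:
    """Register-loss trigger: a disagreement window containing a long run.

    ``min_run`` defaults to 5 because legitimately encoded text reaches runs
    of 3–4 (homopolymeric function codons, category-3 codon junctions) that
    must not break the trace, while camouflage filler injects runs of 6+.
    """

    window: int = 10
    min_run: int = 5

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_run < 2:
            raise ValidationError("dephasing thresholds out of range")


@dataclass
class TracePosition:
    """One read position: 1-based index, per-channel intensity, call, class."""

    index: int
    intensities: dict[str, float]
    call: str
    klass: str


@dataclass
class Trace:
    """A simulated chromatogram: ordered positions with channel intensities."""

    positions: list[TracePosition] = field(default_factory=list)
    primer: str = ""
    template_ids: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def calls(self) -> str:
        return "".join(p.call for p in self.positions)

    @property
    def klasses(self) -> list[str]:
        return [p.klass for p in self.positions]


def _call_and_class(channels: dict[str, float], purity: float) -> tuple[str, str]:
    total = sum(channels.values())
    # Fixed A<C<G<T tie-break keeps consensus deterministic.
    call = max(BASES, key=lambda b: (channels[b], -BASES.index(b)))
    if channels[call] <= 0:
        return "N", HETEROGENEOUS
    klass = HOMOGENEOUS if channels[call] / total >= purity else HETEROGENEOUS
    return call, klass


def simulate_cosequencing(
    mix: TemplateMix,
    primer: PrimerSpec,
    read_length: int = DEFAULT_READ_LENGTH,
    dephasing: DephasingPolicy | None = None,
    purity: float = DEFAULT_PURITY,
    noise_sd: float = 0.0,
    noise_seed: int = 0,
) -> Trace:
    """Simulate co-sequencing of a template mix with a common primer.

    Templates without an annealing site contribute nothing; a template with
    more than one site is ambiguous (an error).  Intensities are exact
    concentration fractions unless ``noise_sd`` adds seeded Gaussian channel
    noise (classification still uses the noiseless signal).
    """
    if read_length < 1:
        raise ValidationError(f"read_length must be >= 1, got {read_length}")
    if not 0.5 < purity <= 1.0:
        raise ValidationError(f"purity threshold must be in (0.5, 1], got {purity}")
    reads: list[tuple[str, float]] = []
    for strand, conc in mix.entries:
        sites = find_anneal_sites(primer, strand)
        if len(sites) > 1:
            raise AmbiguousPrimerError(
                f"primer {primer.name!r} anneals at {len(sites)} sites in {strand.id!r}"
            )
        if not sites:
            continue
        site = sites[0]
        template = (
            strand.sequence if site.template_orientation == AS_GIVEN
            else reverse_complement(strand.sequence)
        )
        reads.append((template[site.offset : site.offset + read_length], conc))
    if not reads:
        raise NoSignalError(f"primer {primer.name!r} has no site in any template")

    length = max(len(r) for r, _ in reads)
    rng = random.Random(noise_seed) if noise_sd > 0 else None
    positions: list[TracePosition] = []
    dephased_from: int | None = None
    for j in range(length):
        channels = {b: 0.0 for b in BASES}
        bases_here = set()
        for read, conc in reads:
            if j < len(read):
                channels[read[j]] += conc
                bases_here.add(read[j])
        call, klass = _call_and_class(channels, purity)
        if dephasing is not None and dephased_from is None and len(bases_here) > 1:
            window = dephasing.window
            for read, _ in reads:
                segment = read[j : j + window]
                if segment and max_homopolymer_run(segment) >= dephasing.min_run:
                    dephased_from = j
                    break
        if dephased_from is not None:
            call, klass = "N", UNRELIABLE
        if rng is not None:
            channels = {
                b: max(0.0, v + rng.gauss(0.0, noise_sd)) for b, v in channels.items()
            }
        positions.append(TracePosition(j + 1, channels, call, klass))
    return Trace(
        positions=positions,
        primer=primer.name,
        template_ids=tuple(s.id for s, _ in mix.entries),
    )


def consensus(trace: Trace) -> str:
    """Concatenated base calls (N at unreliable positions)."""
    if not trace.positions:
        raise ValidationError("cannot take the consensus of an empty trace")
    return trace.calls


def expected_minor_fraction(ratio: float) -> float:
    """Minor-peak intensity share at a two-template mismatch, linear mixing."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio must be within [0, 1], got {ratio}")
    return min(ratio, 1.0 - ratio)
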