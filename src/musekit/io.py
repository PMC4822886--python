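"""File I/O, packaged fixtures, and run configuration.

The packaged fixtures are the wet-lab-validated construct sequences (the
keyboard record pBZ38, the two-strand message pair DNA-1/DNA-2, the six
WWII communication strands n1–n6) and the four sequencing primers, stored
verbatim and verified against SHA-256 checksums at load time: a discrepancy
surfaces as an error, never a silent correction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cosequence import PrimerSpec, Trace, TracePosition
from .dna import Strand, check_dna
from .errors import FixtureError, MusekitError, ValidationError
from .ikey import Button, ButtonKind, IKey, build_reference_ikey

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Strand]:
    """Read strands from FASTA; sequences are upper-cased on read."""
    path = Path(path)
    strands = []
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            strands.append(
                Strand(record.id, str(record.seq).upper(), description=record.description)
            )
    except (ValueError, FileNotFoundError) as exc:
        raise MusekitError(f"cannot parse FASTA {path}: {exc}") from exc
    return strands


def write_fasta(strands: Iterable[Strand], path: str | Path, wrap: int = 70) -> None:
    """Write strands as FASTA, line-wrapped (lossless id + sequence roundtrip)."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description=s.description) for s in strands
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

#: SHA-256 of each fixture sequence, pinned at packaging time.
FIXTURE_CHECKSUMS = {
    "iKey-64": "fbb1ee16f2f5bee1196211450de22d7e73a73d6ffb3c93ad1156ce7b6e188cdf",
    "DNA-1": "b5b811ff97ff233a761fa76fc074bb5ca0fd63e586dd14d6377e3f84244476bf",
    "DNA-2": "9681371d57f4de1fcc6f1468d3f3ab4f9eccdd2b50829cebfaf7349b292de7e3",
    "n1": "7205fdb8fc36fa551d0a1609349fb951be2437f23af243fe5f3cfd2cd1ff4984",
    "n2": "596403924a04b29658ba3fa664cf35997da7ce9b3159854759d0d6bb519c9c84",
    "n3": "fbbc2490f0773789fe87a7c10d6fd28db87fa9fc846184c68bff30d5b74b5a42",
    "n4": "92a46ce2e00b6e0b5ee77820d956c675ec028b7e447a74e33aee18f00951b64f",
    "n5": "f09598ba139ef67f63a950682e8cec20b88fc326725b6847768517fec6dcb0ea",
    "n6": "d3f466f01db0cccb9f71e06b1d330ccbda0ac0c279f6f649cdfd3c5c6ba8095b",
    "Primer_ExternalFw": "f18d00752fef7933a83483a6152144f2249376700081954b38a426bdbdf400a0",
    "Primer_ExternalRv": "4d424217fbf36ace8935cc0f1a4a85d35b7c5d8453da5cb813bcd9d8a2f67d8a",
    "Primer_Key": "8431de827c49a7089e13652fecd55fcd338d56dd9375b5c8ad9e8e28509f1d23",
    "Primer_Message": "052c77e11a844a55dfcfc3e2a82e5b90d6d54444a30d2f8ffc76691406a757fa",
}

#: Construct-name aliases (plasmid names from the source constructs).
FIXTURE_ALIASES = {
    "pBZ38": "iKey-64",
    "pBZ27": "DNA-1",
    "pBZ28": "DNA-2",
    "pBZ29": "n1",
    "pBZ30": "n2",
    "pBZ31": "n3",
    "pBZ32": "n4",
    "pBZ33": "n5",
    "pBZ37": "n6",
}

STRAND_FIXTURES = ("iKey-64", "DNA-1", "DNA-2", "n1", "n2", "n3", "n4", "n5", "n6")
PRIMER_FIXTURES = ("Primer_ExternalFw", "Primer_ExternalRv", "Primer_Key", "Primer_Message")


def _data_text(filename: str) -> str:
    return resources.files("musekit.data").joinpath(filename).read_text()


def _load_fasta_resource(filename: str) -> dict[str, Strand]:
    strands: dict[str, Strand] = {}
    name, desc, chunks = None, "", []
    lines = _data_text(filename).splitlines() + [">"]
    for line in lines:
        if line.startswith(">"):
            if name is not None:
                strands[name] = Strand(name, "".join(chunks).upper(), description=desc)
            header = line[1:].split(None, 1)
            name = header[0] if header else None
            desc = header[1] if len(header) > 1 else ""
            chunks = []
        else:
            chunks.append(line.strip())
    return strands


def _verify(name: str, sequence: str) -> None:
    digest = hashlib.sha256(sequence.encode()).hexdigest()
    if digest != FIXTURE_CHECKSUMS[name]:
        raise FixtureError(f"fixture {name!r} failed its integrity check")


def load_fixture(name: str) -> Strand | PrimerSpec:
    """Return a packaged construct strand or primer, checksum-verified."""
    name = FIXTURE_ALIASES.get(name, name)
    if name in STRAND_FIXTURES:
        strand = _load_fasta_resource("constructs.fasta")[name]
        _verify(name, strand.sequence)
        return strand
    if name in PRIMER_FIXTURES:
        primer = _load_fasta_resource("primers.fasta")[name]
        _verify(name, primer.sequence)
        return PrimerSpec(name, primer.sequence)
    raise FixtureError(
        f"unknown fixture {name!r}; known: {sorted(STRAND_FIXTURES + PRIMER_FIXTURES)}"
    )


def load_construct_strands() -> dict[str, Strand]:
    """All construct fixtures keyed by name, checksum-verified."""
    return {name: load_fixture(name) for name in STRAND_FIXTURES}  # type: ignore[misc]


# ---------------------------------------------------------------------------
# Keyboard configs
# ---------------------------------------------------------------------------

def write_ikey_config(ikey: IKey, path: str | Path) -> None:
    """Write a keyboard as TSV: position, label, codon, kind, category."""
    with open(path, "w") as fh:
        fh.write("position\tlabel\tcodon\tkind\tcategory\n")
        for i, b in enumerate(ikey.buttons, start=1):
            fh.write(f"{i}\t{b.label}\t{b.codon}\t{b.kind.value}\t{b.category.name}\n")


def read_ikey_config(path: str | Path) -> IKey:
    """Read a keyboard TSV written by :func:`write_ikey_config`."""
    buttons = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            li, ci, ki = header.index("label"), header.index("codon"), header.index("kind")
        except ValueError as exc:
            raise MusekitError(f"bad iKey config header in {path}: {exc}") from None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                buttons.append(Button(fields[li], fields[ci], ButtonKind(fields[ki])))
            except (IndexError, ValueError) as exc:
                raise MusekitError(f"bad iKey config line {lineno} in {path}: {exc}") from None
    return IKey(tuple(buttons))


def load_reference_ikey_config() -> IKey:
    """The shipped reference-keyboard fixture (equals build_reference_ikey())."""
    rows = _data_text("ikey64_reference.tsv").splitlines()
    buttons = []
    for line in rows[1:]:
        _, label, codon, kind, _cat = line.split("\t")
        buttons.append(Button(label, codon, ButtonKind(kind)))
    return IKey(tuple(buttons))


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def trace_to_tsv(trace: Trace, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write a trace as TSV: pos, A, C, G, T, call, class (optional # header)."""
    frame = pd.DataFrame(
        {
            "pos": [p.index for p in trace.positions],
            **{b: [p.intensities[b] for p in trace.positions] for b in "ACGT"},
            "call": [p.call for p in trace.positions],
            "class": [p.klass for p in trace.positions],
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def trace_from_tsv(path: str | Path) -> Trace:
    """Read a trace TSV written by :func:`trace_to_tsv`."""
    frame = pd.read_csv(path, sep="\t", comment="#").rename(columns={"class": "klass"})
    positions = [
        TracePosition(
            int(row.pos),
            {b: float(getattr(row, b)) for b in "ACGT"},
            str(row.call),
            str(row.klass),
        )
        for row in frame.itertuples(index=False)
    ]
    return Trace(positions=positions)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated knobs for a pipeline run; recorded in output headers."""

    seed: int = 0
    purity: float = 0.9
    read_length: int = 700
    min_block: int = 9
    dephasing_window: int = 10
    dephasing_min_run: int = 5
    verbosity: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.purity <= 1.0:
            raise ValidationError(f"purity must be in (0.5, 1], got {self.purity}")
        if self.read_length < 1 or self.min_block < 1:
            raise ValidationError("read_length and min_block must be >= 1")
        if self.dephasing_window < 1 or self.dephasing_min_run < 2:
            raise ValidationError("dephasing thresholds out of range")

    def header_lines(self) -> list[str]:
        return [
            f"seed={self.seed} purity={self.purity} read_length={self.read_length} "
            f"min_block={self.min_block} "
            f"dephasing=window:{self.dephasing_window},min_run:{self.dephasing_min_run}"
        ]
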