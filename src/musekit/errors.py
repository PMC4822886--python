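"""Exception hierarchy for musekit.

Every error raised deliberately by the package derives from
:class:`MusekitError`, so callers (and the CLI) can distinguish data errors
from genuine bugs.
"""


class MusekitError(Exception):
    """Base class for all musekit errors."""


class InvalidSequenceError(MusekitError):
    """A string is not a valid DNA sequence over {A, C, G, T}."""


class InvalidCodonError(InvalidSequenceError):
    """A codon is not a length-3 DNA word."""


class ValidationError(MusekitError):
    """A domain object violates its invariants."""


class EncodingError(MusekitError):
    """Plaintext cannot be encoded under the given keyboard."""


class DecodingError(MusekitError):
    """A DNA string cannot be decoded under the given keyboard."""


class MalformedMessageError(DecodingError):
    """The codon stream is structurally broken (e.g. trailing shift)."""


class MalformedRecordError(MusekitError):
    """A serialized keyboard record does not have the expected shape."""


class KeySpecError(MusekitError):
    """A combination-key spec cannot be parsed or resolved."""


class FragmentationError(MusekitError):
    """A text cannot be fragmented into the requested number of parts."""


class ExtractionError(MusekitError):
    """No shared message could be extracted from a strand combination."""


class AnchoringError(MusekitError):
    """An anchor subsequence is absent or ambiguous in a strand."""


class AmbiguousPrimerError(MusekitError):
    """A primer anneals at more than one site in a single template."""


class NoSignalError(MusekitError):
    """No template in the mixture carries an annealing site."""


class FixtureError(MusekitError):
    """A packaged fixture is unknown or fails its integrity check."""
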