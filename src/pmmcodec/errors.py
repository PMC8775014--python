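"""Exception hierarchy shared across the package."""


class PmmError(Exception):
    """Base class for all pmmcodec errors."""


class AlphabetError(PmmError, ValueError):
    """A symbol outside the declared alphabet was encountered."""


class InvalidSpecError(PmmError, ValueError):
    """Inconsistent model configuration (order, gap, block size)."""


class SampleTooShortError(PmmError, ValueError):
    """Sequence shorter than the memory window of the model."""


class NoSupportError(PmmError, ValueError):
    """All weights are zero; no code can be built."""


class NoDataError(PmmError, ValueError):
    """A count table with no observed transitions."""


class InvalidLengthsError(PmmError, ValueError):
    """Codeword lengths violate the Kraft inequality or monotonicity."""


class IncrementOverflowError(PmmError, ValueError):
    """A codelength increment exceeds 1 in the one-bit description scheme."""


class MissingRowError(PmmError, KeyError):
    """A conditional probability row required for coding is unavailable."""


class ContainerFormatError(PmmError, ValueError):
    """Malformed or corrupted compressed container."""
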