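"""Shared exception hierarchy.

Everything this package raises deliberately derives from :class:`DynarefError`
so callers (and the CLI) can distinguish user/data errors from genuine bugs.
"""


class DynarefError(Exception):
    """Base class for all errors raised by dynaref."""


class PileupParseError(DynarefError):
    """A base string (or a field inside it) could not be tokenized."""


class PileupFormatError(DynarefError):
    """Structural problem in a pileup file: bad columns, ordering, types."""


class FastaError(DynarefError):
    """Reference FASTA problem (e.g. duplicate record names)."""


class ConfigurationError(DynarefError):
    """Invalid configuration: thresholds, manifests, population definitions."""


class DomainError(DynarefError, ValueError):
    """Mathematical-domain violation (bad probability vector, zero total)."""


class ContractError(DynarefError):
    """An operation was called outside its stated precondition."""


class BoundsError(DynarefError):
    """A genomic coordinate fell outside its chromosome."""
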