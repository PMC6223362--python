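"""Exception hierarchy.

Every error raised by this package derives from :class:`StructwinError`,
so callers (and the CLI) can distinguish input/contract problems from
genuine bugs with a single ``except``.
"""


class StructwinError(Exception):
    """Base class for all errors raised by structwin."""


class InputError(StructwinError):
    """Bad user input: missing file, unknown chain, incompatible options."""


class ParseError(StructwinError):
    """A structure or sequence file could not be parsed."""


class EmptyStructureError(StructwinError):
    """A structure (or spatial index) contains no eligible polymer residues."""


class FormattingError(StructwinError):
    """A value cannot be represented in a fixed-width PDB field."""


class MetricInapplicableError(StructwinError):
    """A distance metric cannot be evaluated on a residue (e.g. no CA atom)."""


class LowIdentityError(StructwinError):
    """A pairwise alignment fell below the identity floor."""


class MappingFailureError(StructwinError):
    """No reading frame / strand combination maps the alignment to the reference."""


class ContractViolationError(StructwinError):
    """An alignment handed to a statistic still contains gap/ambiguity characters."""


class InsufficientDataError(StructwinError):
    """Too few sequences (or values) for the requested statistic."""


class ScoringError(StructwinError):
    """A user-supplied scoring function raised inside the window engine."""
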