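"""Exception hierarchy.

Exit-code convention for the CLI: validation errors map to exit code 1,
usage errors to 2 (see :mod:`epimap.cli`).
"""


class EpimapError(Exception):
    """Base class for all package errors."""


class FormatError(EpimapError):
    """Malformed input file (bad FASTA record, missing column, bad registry)."""


class ValidationError(EpimapError):
    """Well-formed input that violates a domain invariant."""


class UsageError(EpimapError):
    """The caller asked for something unsupported (bad mode, infeasible design)."""


class OutOfCDSError(ValidationError):
    """A clone lies entirely outside the coding sequence of its reference."""


class DegenerateFragmentError(ValidationError):
    """A clone encodes no complete codon after clamping to the CDS."""


class InconsistentPositivesError(ValidationError):
    """Positive tiling calls share no residue; no single binding region exists."""


class InconsistentNegativesError(ValidationError):
    """Negative tiling calls cover every residue shared by the positives."""


class UnknownGeneError(ValidationError):
    """A prey gene is absent from the reference set / null model."""
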