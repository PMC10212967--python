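"""Exception hierarchy shared across the package.

Exit-code contract used by the CLI: usage/config problems map to
:class:`ConfigError` (exit 1), data/format problems to
:class:`FormatError` (exit 2).
"""


class VarconsError(Exception):
    """Base class for all package errors."""


class ConfigError(VarconsError):
    """Invalid configuration, thresholds, rosters, or CLI usage."""


class FormatError(VarconsError):
    """Malformed or unreadable input data (VCF, FASTA, manifests)."""


class InvalidVariantError(FormatError):
    """A variant record violates the allele contract (empty allele, ref == alt, ...)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ReferenceMismatchError(FormatError):
    """REF allele disagrees with the supplied reference sequence."""


class ContextError(FormatError):
    """Not enough upstream reference context to left-align an indel."""
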