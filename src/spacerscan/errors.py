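"""Exception hierarchy.

Everything raised on bad user input derives from :class:`SpacerScanError`
and from the closest builtin (ValueError/KeyError) so callers can catch
either way.
"""


class SpacerScanError(Exception):
    """Base class for all spacerscan errors."""


class FormatError(SpacerScanError, ValueError):
    """Malformed input file (FASTA/GFF3/gene-set TSV/config)."""


class AlphabetError(SpacerScanError, ValueError):
    """Sequence contains characters outside {A,C,G,T,N}."""


class ReferenceLookupError(SpacerScanError, KeyError):
    """An identifier does not resolve (unknown chromosome, unknown gene)."""


class DegenerateInputError(SpacerScanError, ValueError):
    """Statistically degenerate input (zero variance, all-zero matrix, ...)."""


class ConfigurationError(SpacerScanError, ValueError):
    """Infeasible or inconsistent simulation/run configuration."""
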