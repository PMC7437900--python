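"""Exception hierarchy.

Every error raised by the package derives from :class:`BarcodePCIError`
so callers (and the CLI) can distinguish data problems from bugs.
"""


class BarcodePCIError(Exception):
    """Base class for all package errors."""


class InputError(BarcodePCIError):
    """Empty or unreadable input file."""


class AlignmentError(InputError):
    """Sequences do not share one alignment width."""


class MetadataError(InputError):
    """Metadata table inconsistent with the FASTA records."""


class EmptyDatasetError(BarcodePCIError):
    """An operation produced or received a dataset with no samples."""


class IncomparablePairError(BarcodePCIError):
    """A sequence pair shares zero unambiguous, ungapped columns.

    A p-distance is undefined for such a pair; imputing one silently
    would corrupt nearest-neighbor sets, so the pair is named instead.
    """

    def __init__(self, id_a: str, id_b: str):
        self.id_a = id_a
        self.id_b = id_b
        super().__init__(
            f"samples {id_a!r} and {id_b!r} share no comparable alignment "
            "columns; p-distance is undefined for this pair"
        )


class DomainError(BarcodePCIError):
    """Operation applied outside its domain (e.g. PCI of a singleton)."""


class DegenerateTestError(BarcodePCIError):
    """A test statistic has zero variance (no informative species)."""


class ConfigError(BarcodePCIError):
    """Synthetic-generator configuration is unsatisfiable."""
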