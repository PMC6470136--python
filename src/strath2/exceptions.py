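"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: configuration errors -> 2, data errors
-> 3, numeric errors -> 4.
"""


class Strath2Error(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(Strath2Error):
    """A parameter or configuration value is invalid or degenerate."""

    exit_code = 2


class DataError(Strath2Error):
    """Input data are malformed, misaligned or reference unknown entities."""

    exit_code = 3


class AlignmentError(DataError):
    """Two tables that must share a variant/gene universe do not."""


class InputReferenceError(DataError):
    """An input refers to a SNP/gene absent from the declared universe."""


class EmptyCategoryError(DataError):
    """An annotation category has no member SNPs (or no resolvable genes)."""


class EmptyTargetError(DataError):
    """A target gene list has no overlap with the expression universe."""


class NumericError(Strath2Error):
    """A numeric computation failed (non-PSD matrix, rank deficiency, ...)."""

    exit_code = 4


class CollinearityError(NumericError):
    """The regression design is rank deficient; names offending categories."""

    def __init__(self, categories, message=None):
        self.categories = list(categories)
        super().__init__(
            message
            or "collinear annotation categories in regression design: "
            + ", ".join(map(str, self.categories))
        )
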