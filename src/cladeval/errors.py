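"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`CladevalError`
so callers (and the CLI) can distinguish categorized failures from bugs.
"""


class CladevalError(Exception):
    """Base class for all errors raised by cladeval."""


class TaxonomyStructureError(CladevalError):
    """The taxonomy violates a structural invariant (orphan, cycle, duplicate, no root)."""


class UnknownTaxidError(CladevalError, KeyError):
    """A taxid was queried that does not exist in the taxonomy."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return CladevalError.__str__(self)


class FormatError(CladevalError):
    """An input file does not conform to its declared dialect."""


class ConsistencyError(CladevalError):
    """Two inputs that must agree (e.g. assignments vs. read truth) do not."""


class ParameterError(CladevalError, ValueError):
    """A parameter is outside its documented domain."""


class SpecificationError(CladevalError):
    """An exclusion specification cannot be applied to the given taxonomy."""


class UsageError(CladevalError):
    """An operation was called outside its documented precondition."""
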