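"""Exception hierarchy shared by all pathcausal modules.

The CLI maps these onto exit codes: :class:`UsageError` exits 1, every other
:class:`PathwayError` (format, integrity, lookup) exits 2.
"""


class PathwayError(Exception):
    """Base class for all data-related errors raised by pathcausal."""


class FormatError(PathwayError):
    """The input document is syntactically malformed (bad XML/JSON, unknown
    kind token, missing required field)."""


class IntegrityError(PathwayError):
    """The document is well-formed but violates referential integrity:
    duplicate ids, dangling references, cyclic complex composition."""


class UnknownIdError(PathwayError, KeyError):
    """A caller-supplied id does not resolve within the pathway or graph."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return Exception.__str__(self)


class UsageError(PathwayError, ValueError):
    """The call itself is invalid (bad parameter combination), independent
    of any particular input document."""
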