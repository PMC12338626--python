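"""Exception hierarchy.

All package-raised errors derive from :class:`VaxmapError` so callers
(including the CLI) can distinguish data problems from programming bugs.
"""


class VaxmapError(Exception):
    """Base class for all vaxmap errors."""


class FormatError(VaxmapError):
    """A file or stream is not in the expected format (unparseable,
    missing required column, malformed metadata block)."""


class ValidationError(VaxmapError):
    """Content parsed but violates an invariant (duplicate code, unknown
    identifier, cyclic hierarchy, infeasible fixture spec)."""


class UsageError(VaxmapError):
    """The caller invoked an operation on inputs it is documented not to
    accept (e.g. mapping an ineligible source term)."""
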