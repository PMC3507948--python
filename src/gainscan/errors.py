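"""Exception hierarchy.

Everything raised on bad input derives from :class:`GainscanError` so callers
can catch one type; parse failures carry enough context (id, line, column) to
locate the offending record.
"""


class GainscanError(Exception):
    """Base class for all gainscan errors."""


class FormatError(GainscanError):
    """Malformed input file (bad character, ragged alignment, unparseable field)."""


class InvariantError(GainscanError):
    """A domain-type invariant would be violated (duplicate ids, empty sequence...)."""


class DomainError(GainscanError):
    """Arguments outside an operation's domain (p >= 1 under Poisson, time <= 0...)."""
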