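"""Exception hierarchy.

Every error raised by the library derives from :class:`GsaError` so pipeline
code can distinguish library failures from programming errors.
"""


class GsaError(Exception):
    """Base class for all gsasynth errors."""


class ValidationError(GsaError, ValueError):
    """Input violates a structural contract (cycles, empty corpus, bad matrix)."""


class CycleError(ValidationError):
    """The ontology graph contains a directed cycle."""


class UnknownTermError(GsaError, KeyError):
    """A term identifier is not present in the ontology."""


class NamespaceError(GsaError, ValueError):
    """Unknown namespace, or an operation crossed namespace boundaries."""


class NoCommonAncestorError(GsaError, ValueError):
    """Two terms have no common ancestor (disconnected namespaces)."""


class MissingICError(GsaError, ValueError):
    """An information-content value required by a measure is unavailable."""


class ParseError(GsaError, ValueError):
    """A flat file (OBO/GAF/GMT) could not be parsed."""
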