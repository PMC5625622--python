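"""Exception hierarchy for rdfacets."""


class RdfacetsError(Exception):
    """Base class for all rdfacets errors."""


class ConfigParseError(RdfacetsError):
    """The structure configuration document is malformed.

    Carries a human-readable location (line/column or key path) when the
    underlying parser provides one.
    """


class StructureValidationError(RdfacetsError):
    """The structure configuration violates an invariant.

    The message names the offending entity (database, column, or link).
    """


class ConversionError(RdfacetsError):
    """A table cannot be converted (undeclared column, unknown database)."""


class EmptyQueryError(RdfacetsError):
    """A free-text query is empty after tokenization."""


class QueryContractError(RdfacetsError):
    """A user-supplied SPARQL query does not bind the ``?subject`` variable,
    or a query spec has no search condition at all."""


class SeparatorCollisionError(RdfacetsError):
    """The facet-count separator string occurs in stored values; the engine
    must be reconfigured with a different separator."""


class TransportError(RdfacetsError):
    """A remote SPARQL endpoint could not be reached; carries the endpoint
    identity."""

    def __init__(self, endpoint: str, cause: Exception | None = None):
        self.endpoint = endpoint
        self.cause = cause
        super().__init__(f"SPARQL endpoint unreachable: {endpoint}"
                         + (f" ({cause})" if cause else ""))


class InconsistentCountsError(RdfacetsError):
    """Facet counts are internally inconsistent (e.g. an in-result count
    exceeding the number of result entries)."""
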