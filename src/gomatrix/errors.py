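"""Exception hierarchy for ontology and annotation processing."""


class GomatrixError(Exception):
    """Base class for all package errors."""


class OboFormatError(GomatrixError):
    """Structural problem in an OBO flat file (duplicate id, dangling edge,
    malformed stanza). ``offset`` is the byte offset of the offending stanza
    when known."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)
        self.offset = offset


class CycleError(OboFormatError):
    """The is_a/part_of graph is not acyclic; ``cycle`` lists one offending
    cycle as numeric keys in traversal order."""

    def __init__(self, cycle: list[int]):
        self.cycle = list(cycle)
        pretty = " -> ".join(str(k) for k in self.cycle)
        super().__init__(f"cycle over is_a/part_of edges: {pretty}")


class InvalidAccessionError(GomatrixError):
    """Accession string does not match the ``prefix:digits`` pattern.

    Distinct from an *unknown* (syntactically valid but unregistered) id,
    which is reported through :class:`~gomatrix.obo_model.Resolution`.
    """


class AnnotationFormatError(GomatrixError):
    """Annotation input unusable: empty file, no valid rows, or a column
    specification that never matches."""
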