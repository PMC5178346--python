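"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`EnvotagError` so the CLI can
report failures with the stage name and a clean message instead of a
traceback.
"""


class EnvotagError(Exception):
    """Base class for all pipeline errors."""


class InputError(EnvotagError):
    """Invalid user input (empty FASTA, duplicate headers, bad arguments)."""


class ParseError(EnvotagError):
    """Malformed input file; message carries file context (line/row)."""


class OboParseError(ParseError):
    """Malformed OBO stanza; names the offending line."""


class OntologyCycleError(EnvotagError):
    """The is_a relation contains a cycle; message lists one offending cycle."""


class UnknownTermError(EnvotagError, KeyError):
    """A term identifier is absent from the ontology graph."""


class StoreError(EnvotagError):
    """Metadata store missing, malformed, or violating its schema."""


class SearchError(EnvotagError):
    """External similarity-search invocation failed."""


class MissingDependencyError(SearchError):
    """Aligner executable or database not found before any work started."""
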