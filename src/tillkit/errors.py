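"""Exception hierarchy shared across the toolkit."""


class TillkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TillkitError):
    """An input file is missing required structure (e.g. a named column)."""


class ParseError(TillkitError):
    """A cell or field could not be converted; message carries row/column."""


class BoundsError(TillkitError):
    """A coordinate falls outside the sequence or interval it refers to."""


class ConsistencyError(TillkitError):
    """Cross-referenced inputs disagree (e.g. reference base mismatch)."""


class VocabularyError(TillkitError):
    """A phenotype term is not part of the controlled vocabulary."""


class QueryError(TillkitError):
    """A catalog query names an unknown field."""
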