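"""Exception hierarchy shared across the toolkit."""


class PersentError(Exception):
    """Base class for all errors raised by this package."""


class EmptyDocumentError(PersentError):
    """No sentence survived normalization."""


class EmptyCorpusError(PersentError):
    pass


class DegenerateVocabularyError(PersentError):
    """A topic model cannot be fit on an empty vocabulary."""


class LexiconFormatError(PersentError):
    """Malformed lexicon file (bad column count, non-integer strength)."""


class StrengthRangeError(PersentError):
    """Term strength outside {-5..-1} u {+1..+5}; zero is forbidden."""


class DuplicateTermError(PersentError):
    pass


class WeightError(PersentError):
    """Negative usefulness weight, or all weights zero."""


class LengthMismatchError(PersentError):
    pass


class RatingRangeError(PersentError):
    """Rating outside the 1..5 scale."""


class NonBinaryLabelError(PersentError):
    pass


class SingleClassError(PersentError):
    """AUC needs both classes present."""


class EmptyMatrixError(PersentError):
    pass


class ConfigError(PersentError):
    pass


class CommentFormatError(PersentError):
    """Malformed row in a comments CSV; carries the offending row numbers."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class EmptyFileError(PersentError):
    pass
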