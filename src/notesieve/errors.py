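"""Exception hierarchy for notesieve.

User-facing CLI maps :class:`NoteSieveError` subclasses to exit code 1 and
anything else to exit code 2.
"""


class NoteSieveError(Exception):
    """Base class for all errors raised by notesieve."""


class InvalidCodeError(NoteSieveError):
    """A diagnosis code string is empty or unparseable."""


class CorpusFormatError(NoteSieveError):
    """A corpus file line could not be parsed.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ReferentialIntegrityError(NoteSieveError):
    """An identifier points at an object that does not exist."""


class ConsistencyError(NoteSieveError):
    """Two linked objects disagree (e.g. a note handed to the wrong patient)."""


class EmptyVocabularyError(NoteSieveError):
    """No token survived fitting (empty corpus or min_df too aggressive)."""


class SamplingError(NoteSieveError):
    """A pool cannot supply the requested number of documents."""


class TrainingError(NoteSieveError):
    """Model training preconditions violated (e.g. single-class labels)."""


class FeatureSpaceError(NoteSieveError):
    """Feature matrix does not match the space the model was trained on."""


class ConfigError(NoteSieveError):
    """Invalid run configuration or generator parameters."""
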