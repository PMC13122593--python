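"""Exception hierarchy for cobbgeo."""


class CobbGeoError(Exception):
    """Base class for all cobbgeo errors."""


class PoseLabelParseError(CobbGeoError):
    """A pose-label file line could not be parsed.

    Carries the 1-based line number in ``line_no``.
    """

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class AnnotationValidationError(CobbGeoError):
    """An annotation violates a structural constraint that blocks processing."""


class DegenerateVertebraError(CobbGeoError):
    """An endplate segment has (near-)zero length.

    Carries the vertebra sequence index in ``index``.
    """

    def __init__(self, message: str, index: int | None = None):
        self.index = index
        super().__init__(message)


class LevelAssignmentError(CobbGeoError):
    """Vertebral level numbering could not be anchored or overflows T1–L5."""


class GenerationError(CobbGeoError):
    """Synthetic spine generation produced invalid geometry."""


class AgreementInputError(CobbGeoError):
    """Reader-agreement input does not meet a statistic's preconditions."""
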