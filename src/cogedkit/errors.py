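"""Exception types shared across the toolkit."""


class ConfigurationError(ValueError):
    """A configuration object violates one of its invariants."""


class ProtocolError(RuntimeError):
    """An agent or task deviated from the decision-phase protocol."""


class DomainError(KeyError):
    """A (domain, level) pair has no entry where one is required."""


class DataError(ValueError):
    """A record carries values outside its documented range."""


class IncompleteDataError(ValueError):
    """Required cells are absent; ``missing`` lists the offenders."""

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = list(missing)


class DegenerateInputError(ValueError):
    """Input admits no meaningful answer (zero variance, |r| = 1, ...)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested inference."""


class AlignmentError(ValueError):
    """Participant keys of two inputs do not line up; ``offenders`` lists them."""

    def __init__(self, message: str, offenders=()):
        super().__init__(message)
        self.offenders = list(offenders)
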