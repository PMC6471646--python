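"""Exception hierarchy for the decision-support toolkit."""


class DSTError(Exception):
    """Base class for all toolkit errors."""


class DomainError(DSTError, ValueError):
    """An input value is outside the physiologic or mathematical domain."""


class TableRangeError(DomainError):
    """A lookup age falls outside the range covered by a reference table."""


class UnsupportedAgeBandError(DomainError):
    """The requested age is outside every supported prediction-equation band."""


class ConfigError(DSTError, ValueError):
    """A configuration object (score table, meal plan, deficit) is invalid."""


class IntegrityError(DSTError):
    """Pieces of a report were produced from inconsistent inputs."""
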