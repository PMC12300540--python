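"""Exception hierarchy for the ratoonlight package."""


class RatoonLightError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RatoonLightError, ValueError):
    """A scientific parameter violates its stated domain."""


class MissingWeatherError(RatoonLightError):
    """A growth window is not fully covered by the weather series.

    Carries the first missing date so batch runs can report precisely
    which day of the record is absent.
    """

    def __init__(self, first_missing, window_label: str | None = None):
        self.first_missing = first_missing
        self.window_label = window_label
        where = f" in window {window_label!r}" if window_label else ""
        super().__init__(f"weather series has no record for {first_missing}{where}")


class CoverageError(RatoonLightError):
    """A phenology window extends beyond the available weather record."""


class PhenologyError(RatoonLightError):
    """Stage dates are out of order or fall outside their growth window."""


class InvalidReadingError(RatoonLightError, ValueError):
    """A light-bar reading is physically impossible (e.g. incoming <= 0)."""


class SchemaError(RatoonLightError):
    """An input table does not match the documented schema."""


class DesignError(RatoonLightError):
    """The experimental layout is unbalanced or too small to analyse."""


class ConfigError(RatoonLightError):
    """The run configuration contains unknown or invalid keys."""


class ValidationError(RatoonLightError):
    """Aggregated referential-integrity failures across input tables.

    ``problems`` lists every offending key, so a single run reports all
    gaps instead of failing on the first.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        msg = "input validation failed:\n  " + "\n  ".join(self.problems)
        super().__init__(msg)
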