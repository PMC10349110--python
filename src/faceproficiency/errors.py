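"""Exception hierarchy for the proficiency-test pipeline."""


class FaceProficiencyError(Exception):
    """Base class for all package errors."""


class FormatError(FaceProficiencyError):
    """A data file does not conform to the expected tabular layout."""


class ValidationError(FaceProficiencyError):
    """A value violates a declared invariant (range, type, shape)."""


class DegenerateScaleError(FaceProficiencyError):
    """A score vector carries no rank information (all values identical)."""


class UndefinedStatisticError(FaceProficiencyError):
    """A statistic is undefined for this observer (e.g. a truth class has
    no usable responses, or a rate sits on the 0/1 boundary uncorrected)."""


class EmptyMatrixError(FaceProficiencyError):
    """Too few eligible observers remain after exclusions."""


class SamplingError(FaceProficiencyError):
    """A fusion composition cannot be drawn from the available observers."""


class ConfigError(FaceProficiencyError):
    """A pipeline configuration is malformed or self-contradictory."""
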