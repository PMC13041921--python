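"""Exception hierarchy shared across the toolkit."""


class SatarchError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(SatarchError, ValueError):
    """An argument is outside its documented domain."""


class InputError(SatarchError, ValueError):
    """An input object violates an operation's pre-conditions."""


class PlanError(SatarchError, ValueError):
    """A synthetic-genome plan is internally inconsistent."""


class TrainingError(SatarchError, ValueError):
    """Profile training received unusable labeled monomers."""


class EstimationError(SatarchError, ValueError):
    """A depth-based estimate cannot be formed (e.g. zero baseline)."""


class ClassificationError(SatarchError, ValueError):
    """Activity classification lacks overlapping track bins."""


class StatTestError(SatarchError, ValueError):
    """A statistical test's group-structure requirements are not met."""


class ConfigError(SatarchError, ValueError):
    """A pipeline configuration file is invalid."""
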