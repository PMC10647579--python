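"""Exception hierarchy shared across the package."""


class CavikitError(Exception):
    """Base class for all package-specific errors."""


class InvalidPressureError(CavikitError, ValueError):
    """A pressure input violates SBP > DBP > 0 or a positivity constraint."""


class DegeneratePressureError(InvalidPressureError):
    """SBP == DBP: the log/difference ratio in the stiffness formulas is 0/0."""


class InvalidTimingError(CavikitError, ValueError):
    """A pulse-transit timing is non-positive or otherwise unusable."""


class NegativeBetaError(CavikitError, ValueError):
    """A CAVI value below the device offset implies a negative stiffness beta."""


class ConfigError(CavikitError, ValueError):
    """A configuration object fails validation."""


class DegenerateSampleError(CavikitError, ValueError):
    """A statistical routine received a sample with no usable variation."""


class UndefinedTableError(CavikitError, ValueError):
    """A contingency table has a zero margin; the chi-square test is undefined."""


class CollinearityError(CavikitError, ValueError):
    """The regression design matrix is rank deficient."""


class ContractError(CavikitError, ValueError):
    """A result object is missing a term or field the caller requires."""


class StratificationError(CavikitError, ValueError):
    """An age stratification produced an empty or unusable stratum."""


class SchemaError(CavikitError, ValueError):
    """A cohort file does not conform to the documented column schema."""
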