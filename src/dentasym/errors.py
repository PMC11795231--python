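"""Exception hierarchy for dentasym.

Validation failures (bad files, wrong point counts, unbalanced designs) are
kept distinct from numerical/computation failures so callers — and the CLI —
can distinguish "fix your input" from "the computation broke".
"""


class DentasymError(Exception):
    """Base class for all package errors."""


class ValidationError(DentasymError):
    """Input data violates a structural contract."""


class LandmarkFormatError(ValidationError):
    """A landmark file could not be parsed; message names the line."""


class SchemeMismatchError(ValidationError):
    """A configuration's point count does not match its landmark scheme."""


class DegenerateConfigurationError(DentasymError):
    """A configuration is degenerate (coincident/collinear points)."""


class SingularBendingEnergyError(DentasymError):
    """The thin-plate-spline system for a configuration is singular."""


class ComputationError(DentasymError):
    """A model fit or decomposition failed (separation, rank deficiency...)."""
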