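"""Exception and warning hierarchy for wwfrac.

All validation failures raise subclasses of :class:`ValidationError` so the
CLI can map them to a single exit code (2).
"""


class WWFracError(Exception):
    """Base class for all wwfrac errors."""


class ValidationError(WWFracError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(WWFracError, ValueError):
    """A configuration file, catalog entry or shape tag is invalid."""


class ProtocolError(ValidationError):
    """A fractionation protocol is physically inconsistent.

    Raised e.g. when a retained volume is smaller than the droplet-phase
    volume, which would mean discarding the dextran-rich droplets.
    """


class UndefinedEfficiencyError(ValidationError):
    """Both yields are zero: the efficiency statistic is 0/0."""


class DegenerateFitWarning(UserWarning):
    """The calibration loss is flat over the search bounds.

    Happens when every observation has a partition coefficient clamped at
    the cap (or pinned at 1) for all candidate parameter values, so the
    data carry no information about the interfacial parameter.
    """


class AlsConvergenceWarning(UserWarning):
    """ALS weight iteration hit the iteration cap without converging."""
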