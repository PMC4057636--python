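"""Exception hierarchy shared across the package."""


class TraitlinkError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TraitlinkError, ValueError):
    """A numeric argument violates its stated domain (e.g. variance <= 0)."""


class ConfigurationError(TraitlinkError, ValueError):
    """A configuration object is internally inconsistent."""


class DegenerateItemError(TraitlinkError, ValueError):
    """An item cannot be calibrated (e.g. a single observed category)."""


class DisconnectedLinkingError(TraitlinkError, ValueError):
    """The inventory linking graph is not connected through bridge persons."""


class InsufficientDataError(TraitlinkError, ValueError):
    """Too few observations to compute the requested statistic."""
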