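"""Exception hierarchy for aliasclust."""


class AliasclustError(Exception):
    """Base class for all aliasclust errors."""


class MassLabelError(AliasclustError):
    """A vendor mass label could not be parsed into a mass in Daltons."""


class TableFormatError(AliasclustError):
    """A peak table or design file violates the expected layout."""


class DesignError(AliasclustError):
    """A sample design is internally inconsistent."""


class ImputationError(AliasclustError):
    """Missing values cannot be imputed (e.g. a peak with no data at all)."""


class DegenerateFeatureError(AliasclustError):
    """A peak's replicate-mean vector is constant and cannot be normalized."""


class MassOutOfRangeError(AliasclustError):
    """A mass falls below the lowest bin of the mass-window table."""


class NotTestableError(AliasclustError):
    """Too few usable samples remain to compute a ratio CV."""


class DegenerateClusterError(AliasclustError):
    """A cluster's weighted member sum has (near-)zero norm."""


class ConfigError(AliasclustError):
    """Invalid simulation or run configuration."""
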