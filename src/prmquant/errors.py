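"""Exception hierarchy for prmquant."""


class PrmQuantError(Exception):
    """Base class for all prmquant errors."""


class ConfigurationError(PrmQuantError):
    """Invalid scenario, filter, or scheme configuration."""


class GenerationError(PrmQuantError):
    """Synthetic-data generation produced non-finite or unrepresentable output."""


class InputError(PrmQuantError):
    """Malformed user input (sequences, traces, tables)."""


class IntegrationError(PrmQuantError):
    """Peak integration failed (empty or under-sampled window)."""


class ValidationError(PrmQuantError):
    """Transition validation could not be performed."""


class SelectionError(PrmQuantError):
    """Too few usable transitions for a targeted peptide."""


class NormalizationError(PrmQuantError):
    """A normalization factor is absent or zero in some run."""


class StatsError(PrmQuantError):
    """A statistic is undefined for the given input."""
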