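"""Typed exceptions shared across the pipeline.

The CLI maps these onto distinct exit codes so that configuration mistakes,
malformed data and numerical failures are distinguishable in scripts.
"""


class EffortDDMError(Exception):
    """Base class for package errors."""


class ConfigurationError(EffortDDMError):
    """Invalid task design, cohort spec, fit config or pipeline config."""


class DataError(EffortDDMError):
    """Malformed or inconsistent input tables."""


class NumericalError(EffortDDMError):
    """Estimation or sampling failure (non-convergence, rank deficiency...)."""
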