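"""Exception hierarchy.

Two families of failure are distinguished so callers (and the CLI) can
report them differently: a *configuration* error means the constants,
thresholds or parameters supplied to the pipeline are unusable; an
*input* error means a data table violates an invariant (negative
concentration, empty vector, ...).
"""


class PTEWaterError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PTEWaterError):
    """Invalid or missing configuration (thresholds, parameters, columns)."""


class InputError(PTEWaterError):
    """Invalid data values (negative concentrations, unparseable cells, ...)."""
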