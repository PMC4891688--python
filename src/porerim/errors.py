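"""Exception hierarchy shared across the package."""


class PoreRimError(Exception):
    """Base class for all package errors."""


class ValidationError(PoreRimError, ValueError):
    """A domain-type invariant was violated; the message names the field."""


class ParameterError(PoreRimError, ValueError):
    """A parameter combination is outside its allowed operating range."""


class DegenerateRegionError(PoreRimError, ValueError):
    """Cluster area meets or exceeds the region area; density is undefined."""


class IllConditionedError(PoreRimError, ValueError):
    """Regression design has no spread in the predictor."""


class EmptyInputError(PoreRimError, ValueError):
    """An operation requiring at least one datum received none."""


class PairedInputError(PoreRimError, ValueError):
    """Images and annotations could not be matched one-to-one."""
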