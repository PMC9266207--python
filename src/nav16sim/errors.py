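"""Exception hierarchy shared across the package."""


class Nav16SimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(Nav16SimError, ValueError):
    """A rate constant, conductance or protocol parameter is out of range."""


class IntegrationInstabilityError(Nav16SimError, RuntimeError):
    """Occupancies left [0, 1] beyond tolerance during propagation."""


class ProtocolMismatchError(Nav16SimError, ValueError):
    """A measurement window does not fit the sweep it was asked about."""


class NoReversalError(Nav16SimError, ValueError):
    """An I-V relation has no zero crossing on its ascending limb."""


class FitError(Nav16SimError, RuntimeError):
    """Nonlinear least squares failed to converge or produced invalid output."""


class SweepParseError(Nav16SimError, ValueError):
    """A sweep CSV file is malformed (ragged rows, bad header, ...)."""
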