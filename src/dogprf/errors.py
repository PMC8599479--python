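"""Exception types shared across the package."""


class DogPrfError(Exception):
    """Base class for all package errors."""


class ParameterError(DogPrfError, ValueError):
    """A model parameter is outside its mathematical domain."""


class InputError(DogPrfError, ValueError):
    """An input array or value is malformed."""


class GridMismatchError(DogPrfError, ValueError):
    """Arrays defined on incompatible visual-field grids."""


class ConfigError(DogPrfError, ValueError):
    """A configuration is inconsistent or incomplete."""


class DegenerateSignalError(DogPrfError, ValueError):
    """A signal is constant (or otherwise degenerate) where variation is required."""


class DegenerateDesignError(DogPrfError, ValueError):
    """A GLM design matrix is rank deficient (e.g. constant prediction)."""


class StateError(DogPrfError, ValueError):
    """An operation received data in the wrong preprocessing state."""
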