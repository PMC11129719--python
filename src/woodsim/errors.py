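"""Shared exception types for the woodsim pipeline."""


class WoodsimError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(WoodsimError, ValueError):
    """An argument is outside its documented range."""


class DesignError(WoodsimError, ValueError):
    """A triplet design references unknown items or violates balance."""


class ConfigurationError(WoodsimError, ValueError):
    """Mutually incompatible configuration values."""


class DataError(WoodsimError, ValueError):
    """Malformed or inconsistent input data."""


class DegenerateModelError(WoodsimError, RuntimeError):
    """A fitted model collapsed (e.g. zero retained dimensions)."""


class DivergenceError(WoodsimError, RuntimeError):
    """Optimization produced a non-finite loss."""
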