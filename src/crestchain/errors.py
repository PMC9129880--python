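"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or pipeline configuration is invalid before any compute."""


class ValidationError(ValueError):
    """An input table or state sequence violates its format contract."""


class NumericalError(RuntimeError):
    """A simulation produced non-finite state."""


class InapplicableCriterionError(ValueError):
    """A score was requested on a trajectory it is not defined for."""


class InsufficientSampleError(ValueError):
    """A statistical routine received fewer observations than it requires."""
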