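"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class NumericalAccuracyError(RuntimeError):
    """A quadrature result failed its convergence contract."""


class DegenerateDataError(ValueError):
    """The data carry no information about the parameter being estimated."""


class GridMismatchError(ValueError):
    """Profiles that must share an interval grid do not."""


class MissingCellError(ValueError):
    """A repeated-measures design has an empty subject x level cell."""


class SamplerHealthError(RuntimeError):
    """MCMC acceptance rate left its admissible band after tuning."""


class InsufficientSamplesError(ValueError):
    """Too few posterior samples to summarise."""


class FitFailureError(RuntimeError):
    """All optimiser starts failed to converge."""


class InvalidNestingError(ValueError):
    """The 'full' model fits worse than its nested reduction."""
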