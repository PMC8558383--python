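"""Exception types shared across the toolkit."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class AxisMismatchError(InvalidArgumentError):
    """Traces or spectra that should share an axis do not."""


class EmptySelectionError(InvalidArgumentError):
    """A band or region selection matched no grid points."""


class SingularSystemError(ArithmeticError):
    """A penalized least-squares system has no unique solution."""


class RankDeficiencyError(InvalidArgumentError):
    """More latent components requested than the data support."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""
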