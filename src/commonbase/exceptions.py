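"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """Input data violates a documented precondition (bad efficiency, empty
    reference set, malformed table row, ...)."""


class ExtrapolationError(ValidationError):
    """A requested evaluation point lies outside the observed range of the
    independent variable.  Relative-expression predictions are only defensible
    within the range the regression was fitted on; pass
    ``allow_extrapolation=True`` to downgrade this to a warning."""


class HeterogeneousSlopesError(RuntimeError):
    """ANCOVA refused: the homogeneity-of-slopes test rejected parallelism.

    Carries the offending :class:`~commonbase.ancova.InteractionTest` as
    ``self.test`` so callers can report F, degrees of freedom and p.
    """

    def __init__(self, message, test):
        super().__init__(message)
        self.test = test


class EfficiencyWarning(UserWarning):
    """Amplification efficiency is implausibly high (E > 2.2, i.e. more than
    perfect doubling plus margin) but was accepted."""


class ExtrapolationWarning(UserWarning):
    """Evaluation outside the observed x-range proceeded under an explicit
    override."""
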