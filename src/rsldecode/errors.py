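"""Exception types shared across the package."""


class RSLError(ValueError):
    """Base class for rsldecode validation and computation errors."""


class DegenerateItemError(RSLError):
    """An item's pattern vector is degenerate (all-zero or constant) for the
    requested similarity measure; the offending item is named in the message."""


class UndefinedCorrelationError(RSLError):
    """A correlation is requested over a zero-variance set of values."""


class FoldPlanError(RSLError):
    """A stratified fold plan with exact domain balance is infeasible."""


class RankDeficientError(RSLError):
    """OLS requested on a rank-deficient design without the pseudo-inverse
    opt-in; infinitely many coefficient matrices fit the training data."""
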