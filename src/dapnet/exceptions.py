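"""Shared exception and warning types."""


class DapnetError(Exception):
    """Base class for all package errors."""


class ShapeMismatch(DapnetError):
    """Operand shapes are inconsistent with the operation's contract."""


class DegenerateInput(DapnetError):
    """Input is degenerate for the requested operation (e.g. zero-trace covariance)."""


class ConfigError(DapnetError):
    """Invalid model or training configuration."""


class MissingBranchInput(DapnetError):
    """The gate selected a branch whose input was not supplied."""


class EmptyClass(DapnetError):
    """A class folder contains no readable images."""


class InsufficientClass(DapnetError):
    """A class has too few items to split."""


class TargetBelowCurrent(DapnetError):
    """Balancing target is below the current class count."""


class UnknownLabel(DapnetError):
    """A label is outside the declared class-name list."""


class SingleClassInput(DapnetError):
    """ROC requested but only one class is present (no positives or no negatives)."""


class DegenerateVariance(DapnetError):
    """Paired t-test on differences with zero variance."""


class EmptyDataset(DapnetError):
    """Training or evaluation requested on an empty dataset."""


class NonFiniteLoss(DapnetError):
    """Loss became NaN or infinite during training."""


class NotConvergedWarning(UserWarning):
    """Newton-Schulz iteration did not reach the residual tolerance."""
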