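"""Exception types shared across the package."""


class PrcMatchError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(PrcMatchError, ValueError):
    """Unknown experiment/condition pair or invalid configuration value."""


class ContractError(PrcMatchError, ValueError):
    """An operation was called outside its documented preconditions."""


class PoolDepletionError(PrcMatchError, RuntimeError):
    """The trial-unique shape-id pool has been exhausted."""


class DegenerateVarianceError(ContractError):
    """A t statistic is undefined because the relevant variance is zero."""


class UndefinedRatioError(PrcMatchError, ZeroDivisionError):
    """The within:between saccade ratio is undefined (no between-item saccades).

    Carries the two component averages so callers can still report them.
    """

    def __init__(self, within_total_avg: float, between_total_avg: float):
        self.within_total_avg = within_total_avg
        self.between_total_avg = between_total_avg
        super().__init__(
            f"within:between ratio undefined: (Within/Total)Av={within_total_avg}, "
            f"(Between/Total)Av={between_total_avg}"
        )
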