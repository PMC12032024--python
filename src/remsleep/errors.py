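"""Exception types shared across the pipeline."""


class RemSleepError(Exception):
    """Base class for package errors."""


class UndefinedMetric(RemSleepError):
    """A metric's precondition fails (e.g. TST requested on a night with no sleep).

    Absence that is part of a metric's normal range (no REM period -> no RD1)
    is returned as ``None``; this exception marks inputs for which the metric
    has no meaning at all.
    """


class DegenerateSample(RemSleepError):
    """A statistical routine received a sample it cannot operate on
    (constant values, empty group, no paired observations)."""


class SamplingRateTooLow(RemSleepError):
    """EOG sampling rate is below twice the detection band's upper edge."""


class MalformedFile(RemSleepError):
    """An input file does not parse under the expected dialect."""
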