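"""Exception hierarchy for vfshock."""


class VfShockError(Exception):
    """Base class for all vfshock errors."""


class InvalidArgumentError(VfShockError, ValueError):
    """An argument violates a documented precondition."""


class EpisodeUnavailableError(VfShockError):
    """The recording does not cover the requested pre-shock window."""


class MalformedSequenceError(VfShockError, ValueError):
    """A patient's shock sequence has gaps, duplicates or inconsistent ids."""


class SchemaError(VfShockError, ValueError):
    """A file or table does not match the expected schema."""


class DegenerateTrainingError(VfShockError, ValueError):
    """Training data cannot support a fit (single class, separation, ...)."""


class UndefinedRocError(VfShockError, ValueError):
    """ROC analysis requires both outcome classes."""


class TestUndefinedError(VfShockError, ValueError):
    """A statistical test's preconditions are not met."""

    __test__ = False  # not a pytest class, despite the name
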