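"""Exception hierarchy shared across the package.

The CLI maps these onto distinct process exit codes, so every module raises
through this hierarchy rather than bare ValueError/OSError where the failure
is meaningful to a pipeline user.
"""


class RdsUnetError(Exception):
    """Base class for all package errors."""


class SpecificationError(RdsUnetError, ValueError):
    """A configuration value violates its documented invariant."""


class ShapeError(RdsUnetError, ValueError):
    """An array has the wrong shape/channel count for the requested operation."""


class FormatError(RdsUnetError, ValueError):
    """An on-disk file is structurally invalid (bad mask index, unknown label...)."""


class DataIOError(RdsUnetError, OSError):
    """A dataset path is missing or unwritable."""


class DivergenceError(RdsUnetError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, step: int, value: float):
        self.epoch, self.step, self.value = epoch, step, value
        super().__init__(
            f"non-finite training loss ({value!r}) at epoch {epoch}, step {step}"
        )


class UndefinedMetricError(RdsUnetError, ValueError):
    """A metric has no valid class to average over (all denominators zero)."""
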