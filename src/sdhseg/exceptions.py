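"""Exception types raised across the package."""


class SdhsegError(Exception):
    """Base class for package errors."""


class EmptyTargetSet(SdhsegError):
    """A nearest-neighbour query was made against an empty point set."""


class ShapeMismatch(SdhsegError):
    """Two grids that must share a shape do not."""


class InvalidWeights(SdhsegError):
    """Loss weights are invalid (e.g. both zero or negative)."""


class InvalidShape(SdhsegError):
    """An input spatial shape is incompatible with the model architecture."""


class NonFiniteGradient(SdhsegError):
    """A non-finite loss or gradient was encountered during optimisation."""


class InvalidSplit(SdhsegError):
    """Dataset split fractions do not sum to one."""
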