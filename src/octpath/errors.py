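"""Exception hierarchy shared by all octpath modules."""


class OctPathError(Exception):
    """Base class for all octpath errors."""


class ValidationError(OctPathError, ValueError):
    """An input violates a documented precondition or invariant."""


class ConfigurationError(OctPathError, ValueError):
    """A sidecar or configuration document is missing required keys."""


class InfeasiblePathError(OctPathError):
    """No admissible boundary path exists under the given constraints."""


class SegmentationOrderingError(OctPathError):
    """The four boundaries violate their anatomical ordering.

    Carries the offending column indices so a caller can place anchors
    exactly where the automatic segmentation failed.
    """

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(int(c) for c in columns)
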