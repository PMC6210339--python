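"""Exception hierarchy."""


class CavError(Exception):
    """Base class for all package errors."""


class InvalidPoseError(CavError):
    """A pose quaternion is degenerate (zero norm or non-finite)."""


class FormatError(CavError):
    """A dataset file does not conform to the pose-CSV/manifest schema."""


class MetricError(CavError):
    """A metric's preconditions are not met (e.g. recording too short)."""


class ModelError(CavError):
    """A trained model is missing or inconsistent with the request."""
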