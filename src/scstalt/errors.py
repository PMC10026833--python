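"""Exception hierarchy. Everything raised on purpose derives from StaltError."""


class StaltError(Exception):
    """Base class for all scstalt errors."""


class FormatError(StaltError):
    """An on-disk artifact is malformed (dimension/id mismatch, bad header)."""


class ValidationError(StaltError):
    """In-memory data violates a container invariant (negative counts, dupes)."""


class DegenerateTrajectoryError(StaltError):
    """Pseudotime carries no ordering information (all values identical)."""


class FitError(StaltError):
    """Spline regression could not be fitted (rank-deficient basis)."""


class EmptyKernelError(StaltError):
    """No gene passed the dynamic-gene selection; the kernel would be empty."""


class GeneMismatchError(StaltError):
    """Query shares too few kernel genes for a meaningful transfer."""


class UndefinedSimilarityError(StaltError):
    """Cosine similarity requested for a zero-norm vector."""
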