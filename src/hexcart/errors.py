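"""Exception hierarchy."""


class HexcartError(RuntimeError):
    """Base class for all pipeline errors."""


class MeshingError(HexcartError):
    """A cartilage meshing stage failed; the orchestrator may fall back."""


class StrategyFailure(MeshingError):
    """A sweep-grid strategy produced insufficient ray coverage."""


class QualityError(MeshingError):
    """Quality optimization hit its iteration guard before reaching target."""

    def __init__(self, message, worst=None):
        super().__init__(message)
        self.worst = worst or []


class DegenerateClassificationError(MeshingError):
    """A six-node element configuration could not be classified."""

    def __init__(self, message, element_ids=()):
        super().__init__(message)
        self.element_ids = list(element_ids)


class BlendError(MeshingError):
    """Cartilage-to-bone blending could not produce an intersection-free edge."""
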