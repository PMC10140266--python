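"""Exception hierarchy."""


class NesfeError(Exception):
    """Base class for all package errors."""


class ParseError(NesfeError, ValueError):
    """A file or string could not be parsed."""


class ChargeTieError(NesfeError, ValueError):
    """Modal net charge is tied; the caller must choose which series to keep."""


class InsufficientCommonSubstructureError(NesfeError, ValueError):
    """MCS between two molecules is below the minimum heavy-atom threshold."""


class McsTimeoutError(NesfeError, RuntimeError):
    """MCS search exceeded its time budget."""


class InsufficientOverlapError(NesfeError, ValueError):
    """Forward and reverse work distributions do not overlap enough to
    bracket the maximum-likelihood free energy."""


class DisconnectedMapError(NesfeError, ValueError):
    """Perturbation map (or edge-result graph) is not connected."""


class WorkflowConfigError(NesfeError, ValueError):
    """Workflow configuration is invalid."""


class WorkflowStepError(NesfeError, RuntimeError):
    """A workflow step failed during execution."""

    def __init__(self, step_name: str, cause: str):
        super().__init__(f"step '{step_name}' failed: {cause}")
        self.step_name = step_name
        self.cause = cause
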