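"""Exception hierarchy shared across the package."""


class IfacecovError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(IfacecovError, ValueError):
    """Invalid or infeasible user-supplied parameter."""


class StructureError(IfacecovError, ValueError):
    """Problem with a parsed or constructed structure."""


class UnknownElementError(StructureError):
    """Atom element has no van der Waals radius and no fallback is configured."""


class AlignmentError(IfacecovError, ValueError):
    """Malformed or inconsistent pairwise alignment."""


class PipelineError(IfacecovError, RuntimeError):
    """Stage failure inside the orchestrated pipeline; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
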