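"""Exception hierarchy for scolibeam."""


class ScolibeamError(Exception):
    """Base class for all scolibeam errors."""


class MidlineValidationError(ScolibeamError, ValueError):
    """A midline coordinate series violates a structural invariant."""


class MidlineParseError(ScolibeamError, ValueError):
    """A midline CSV could not be parsed into numeric columns."""


class FitError(ScolibeamError, ValueError):
    """Polynomial fitting failed (e.g. rank-deficient design matrix)."""


class BeamModelError(ScolibeamError, ValueError):
    """The beam-column solve cannot proceed with the given inputs."""


class DegenerateLoadError(BeamModelError):
    """The effective axial load is zero: the beam-column equation
    degenerates to the pure-lateral (simple bending) case, which the
    closed-form solver does not cover. Use the numeric solver."""


class TargetUnreachableError(ScolibeamError, ValueError):
    """The displacement target cannot be bracketed by the load interval."""


class PipelineError(ScolibeamError, RuntimeError):
    """A pipeline stage failed; carries the stage name and a hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        text = f"[{stage}] {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)
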