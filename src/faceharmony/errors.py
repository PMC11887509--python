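"""Exception hierarchy for the faceharmony package."""


class FaceHarmonyError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(FaceHarmonyError):
    """A construction line or calibration segment collapsed to a point."""


class MissingLandmarkError(FaceHarmonyError):
    """A required landmark is absent from the set."""

    def __init__(self, name: str, context: str = ""):
        self.landmark = name
        msg = f"missing required landmark {name!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class UnknownLandmarkError(FaceHarmonyError):
    """A landmark name outside the fixed vocabulary was supplied."""


class InvalidLandmarkSetError(FaceHarmonyError):
    """Landmark coordinates violate a structural invariant."""


class InvalidMeasurementError(FaceHarmonyError):
    """A measurement value is outside its admissible range."""


class DegenerateMarginError(FaceHarmonyError):
    """A contingency table has a zero row or column margin."""


class InvalidDeformationError(FaceHarmonyError):
    """A synthetic deformation broke the superior-to-inferior ordering."""


class CohortSchemaError(FaceHarmonyError):
    """A cohort CSV record failed validation."""

    def __init__(self, message: str, line: int | None = None, path: str | None = None):
        self.line = line
        self.path = path
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class PipelineError(FaceHarmonyError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
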