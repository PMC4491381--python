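"""Exception hierarchy for the cinelv pipeline.

Stage-specific errors carry the name of the pipeline stage that failed so
that a batch driver can report *where* a case broke, not just that it did.
"""


class CineLVError(Exception):
    """Base class for all cinelv errors."""


class MetadataError(CineLVError):
    """A required geometry/timing field is missing or invalid on disk."""


class SchemaVersionError(CineLVError):
    """A contour JSON file declares an unsupported schema version."""


class DegenerateContourError(CineLVError):
    """A contour is too small or collapsed to be rasterized or deformed."""


class LVNotFoundError(CineLVError):
    """No bright blood-pool candidate survived smoothing and thresholding.

    Mirrors the one failure mode the method is known to have on severely
    artifacted images: the heart locator finds nothing usable and the whole
    pipeline aborts at its first stage.
    """

    stage = "locate_lv_center"


class StageError(CineLVError):
    """Pipeline failure annotated with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
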