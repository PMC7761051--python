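"""Exception hierarchy shared across the pipeline."""


class PromidiagError(Exception):
    """Base class for all package-specific errors."""


class ConflictingOutcomeError(PromidiagError, ValueError):
    """The same (compound, target) pair was recorded with two different outcomes."""


class MalformedRecordError(PromidiagError, ValueError):
    """A file row could not be parsed; carries the offending line number."""


class UnknownCompoundError(PromidiagError, KeyError):
    """A compound identifier is not present in the activity matrix."""


class MissingRecordError(PromidiagError, ValueError):
    """A matrix compound has no library record during curation."""


class StructureError(PromidiagError, ValueError):
    """A SMILES string could not be parsed; carries the input string."""


class ConfigError(PromidiagError, ValueError):
    """A configuration object or file violates its invariants."""


class PipelineStageError(PromidiagError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
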