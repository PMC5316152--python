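"""Exception hierarchy shared across the package."""


class RibotransError(Exception):
    """Base class for all package errors."""


class ParameterError(RibotransError, ValueError):
    """An argument violates an operation's contract."""


class ModelError(RibotransError, ValueError):
    """A gene model violates its coordinate invariants."""


class GenerationError(RibotransError, ValueError):
    """The synthetic-data generator received inconsistent inputs."""


class InputError(RibotransError, ValueError):
    """A file could not be read or is malformed; message names file and line."""


class DegenerateInputError(RibotransError, ValueError):
    """An input is formally valid but statistically unusable (e.g. empty library)."""


class ScoringError(RibotransError, ValueError):
    """A gene set cannot be scored (empty member or complement side)."""


class SequenceError(RibotransError, ValueError):
    """A CDS sequence violates the coding-sequence contract."""


class PipelineError(RibotransError, RuntimeError):
    """A pipeline stage failed; message names the stage and cause."""
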