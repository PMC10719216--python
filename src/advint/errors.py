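"""Exception hierarchy shared by every stage of the pipeline."""


class AdvintError(Exception):
    """Base class for all package errors."""


class ParameterError(AdvintError, ValueError):
    """An argument value is outside its documented range."""


class DimensionError(AdvintError, ValueError):
    """Shapes of matrices, label vectors or network specs disagree."""


class FormatError(AdvintError, ValueError):
    """An on-disk file violates its declared format."""


class ConfigError(AdvintError, ValueError):
    """An experiment configuration fails validation."""


class DivergenceError(AdvintError, RuntimeError):
    """Optimization produced non-finite values; message names the epoch/step."""


class LabelError(AdvintError, KeyError):
    """A label or class index is unknown to the model or dataset."""


class StageError(AdvintError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
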