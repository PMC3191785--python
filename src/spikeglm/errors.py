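"""Exception hierarchy shared across the package."""


class SpikeGLMError(Exception):
    """Base class for all spikeglm errors."""


class ValidationError(SpikeGLMError, ValueError):
    """Invalid arguments or inconsistent data structures."""


class ParseError(SpikeGLMError, ValueError):
    """Malformed input file; message carries the offending line number."""


class NumericalError(SpikeGLMError, ArithmeticError):
    """Non-finite intensities or other numerical failure."""


class ConvergenceError(SpikeGLMError, RuntimeError):
    """Optimizer failed to converge within the iteration budget."""
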