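"""Package exception hierarchy."""


class CvdpmError(Exception):
    """Base class for all package errors."""


class ValidationError(CvdpmError, ValueError):
    """Invalid input data (negative counts, non-normalized distributions...)."""


class ConfigurationError(CvdpmError, ValueError):
    """Incomplete or inconsistent model configuration (missing betas...)."""


class SimulationError(CvdpmError, RuntimeError):
    """Numerical failure during simulation (probability overflow...)."""
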