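"""Exception types raised by liftbn."""


class LiftbnError(Exception):
    """Base class for all liftbn errors."""


class ConfigurationError(LiftbnError):
    """A scenario or parameter-table entry is missing, unknown, or invalid."""


class InferenceError(LiftbnError):
    """Posterior inference failed (e.g. evidence impossible under the prior)."""
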