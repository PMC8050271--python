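"""Exception types shared across the package."""


class ImksurvError(Exception):
    """Base class for package-specific errors."""


class DataValidationError(ImksurvError, ValueError):
    """A survival table or observation failed validation (message names the row)."""


class ConfigError(ImksurvError, ValueError):
    """A parameter file or fit configuration is malformed (message names the field)."""


class IdentifiabilityError(ImksurvError, ValueError):
    """The experimental design cannot constrain the requested free parameters."""


class UnreachableTargetError(ImksurvError, ValueError):
    """The requested isoeffect survival level cannot be reached by adding dose."""


class ConvergenceError(ImksurvError, RuntimeError):
    """All optimizer restarts failed, or a root solve did not converge."""
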