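"""Exception hierarchy for pathsim."""


class PathsimError(Exception):
    """Base class for all pathsim errors."""


class ConfigError(PathsimError, ValueError):
    """A profile, model or experiment configuration is infeasible or malformed."""


class DataError(PathsimError, ValueError):
    """Input data violate a precondition (e.g. no imputation donor available)."""


class InvalidSwapError(PathsimError, ValueError):
    """A rectangle-swap proposal does not satisfy the crossed-value condition."""


class DegenerateMatrixError(PathsimError, RuntimeError):
    """No valid rectangle swap could be found in a bounded number of attempts."""


class ExpansionStallError(PathsimError, RuntimeError):
    """Population expansion stopped accepting new rows for too many epochs."""


class SplitError(PathsimError, ValueError):
    """A train/test partition could not be formed as requested."""
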