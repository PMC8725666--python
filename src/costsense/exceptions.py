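"""Exception hierarchy for costsense."""


class CostsenseError(Exception):
    """Base class for all costsense errors."""


class ValidationError(CostsenseError, ValueError):
    """Invalid argument or configuration."""


class ArffParseError(CostsenseError, ValueError):
    """Malformed ARFF input (includes the offending line when known)."""


class UnsupportedTaskError(CostsenseError, ValueError):
    """The task is outside the binary-classification scope (e.g. >2 classes)."""


class FeatureTypeError(CostsenseError, TypeError):
    """A feature attribute is not numeric."""


class MissingValueError(CostsenseError, ValueError):
    """The dataset contains missing values, which are rejected by policy."""


class DegenerateInputError(CostsenseError, ValueError):
    """Input is degenerate for the requested computation (e.g. one class only)."""


class SolverError(CostsenseError, RuntimeError):
    """An underlying numerical solver failed; carries its diagnostics."""
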