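"""Exception hierarchy.

ValidationError covers malformed inputs and inconsistent designs (CLI exit
code 2); ConvergenceError covers a non-converged empirical-Bayes solve
(CLI exit code 3).
"""


class MCombatError(Exception):
    """Base class for all package errors."""


class ValidationError(MCombatError):
    """Input data, design, or configuration failed validation."""


class ConvergenceError(MCombatError):
    """The empirical-Bayes fixed-point iteration did not converge."""
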