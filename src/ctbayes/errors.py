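"""Exception hierarchy shared across the package."""


class CtBayesError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CtBayesError):
    """A configuration object or file is invalid."""


class FormatError(CtBayesError):
    """An input file violates the expected tabular format."""


class InputError(CtBayesError):
    """Arguments are structurally valid but unusable (empty groups, too few candidates, ...)."""


class ConvergenceError(CtBayesError):
    """An optimizer failed to converge.

    Carries the best point found so callers can inspect or fall back.
    """

    def __init__(self, message, best_params=None, diagnostics=None):
        super().__init__(message)
        self.best_params = best_params
        self.diagnostics = diagnostics or {}
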