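"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A structured input-validation failure naming the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class VialDataError(ValueError):
    """Malformed vial-level data; carries the offending (1-based) file lines."""

    def __init__(self, message: str, lines=None):
        self.lines = list(lines) if lines is not None else []
        super().__init__(message)


class FitConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        self.diagnostics = diagnostics
        super().__init__(message)


class SeparationError(RuntimeError):
    """Perfect separation encountered while fitting a binomial GLM."""


class CalibrationError(RuntimeError):
    """Attack-coefficient calibration could not reach the target band."""

    def __init__(self, message: str, achieved=None):
        self.achieved = achieved
        super().__init__(message)


class SimulationError(RuntimeError):
    """Non-finite state encountered during a simulation run."""

    def __init__(self, message: str, generation=None, state=None):
        self.generation = generation
        self.state = state
        super().__init__(message)
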