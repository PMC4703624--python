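"""Exception hierarchy.

Exit-code mapping used by the CLI: parse errors -> 2, validation errors -> 3,
convergence errors -> 4.
"""


class PoolHeritError(Exception):
    """Base class for all package errors."""


class ValidationError(PoolHeritError, ValueError):
    """Invalid argument or inconsistent input data."""


class ParseError(PoolHeritError, ValueError):
    """Malformed input file; message carries the file and line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc += ": "
        super().__init__(loc + message)
        self.path = path
        self.line = line


class DegenerateDataError(PoolHeritError, ValueError):
    """Computation undefined for this input (e.g. zero scaling constant)."""


class ConvergenceError(PoolHeritError, RuntimeError):
    """REML iteration failed to converge; carries the iteration trajectory."""

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = history if history is not None else []
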