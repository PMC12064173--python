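"""Exception hierarchy.

``PsifoldError`` covers bad user input (CLI exit code 3),
``NumericalError`` covers runtime numerical failure (CLI exit code 4).
"""


class PsifoldError(ValueError):
    """Invalid input: bad sequence, malformed file, broken precondition."""


class ParseError(PsifoldError):
    """Malformed input file; carries a line number when available."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class NumericalError(RuntimeError):
    """Objective became non-finite or a DP over/underflowed irrecoverably."""
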