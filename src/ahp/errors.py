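"""Exception types and the shared validation-finding record."""

from __future__ import annotations

from dataclasses import dataclass


class AHPError(Exception):
    """Base class for all errors raised by this package."""


class ModelParseError(AHPError):
    """A hierarchy document does not conform to the model schema."""


class ModelValidationError(AHPError):
    """A parsed hierarchy violates a structural invariant."""


class JudgmentError(AHPError):
    """A judgment table or comparison matrix is malformed."""


class ConvergenceError(AHPError):
    """Power iteration failed to converge within the iteration cap."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class ScenarioError(AHPError):
    """A sensitivity scenario specification is invalid."""


@dataclass(frozen=True)
class Finding:
    """One validation finding: ``severity`` is ``"error"`` or ``"warning"``,
    ``path`` locates the offending element, ``message`` explains it."""

    severity: str
    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.path}: {self.message}"


def errors_only(findings: list[Finding]) -> list[Finding]:
    return [f for f in findings if f.severity == "error"]
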