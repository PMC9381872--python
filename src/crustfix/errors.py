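"""Exception hierarchy for the crustfix pipeline."""

from __future__ import annotations


class CrustfixError(Exception):
    """Base class for all crustfix errors."""


class ConfigurationError(CrustfixError):
    """A configuration is incomplete or inconsistent (e.g. a missing site-season)."""


class CalibrationError(CrustfixError):
    """GC calibration is impossible (non-positive standard peak)."""


class InvalidAssayError(CrustfixError):
    """A 15N2 assay violates its preconditions (e.g. headspace below air)."""


class EstimationError(CrustfixError):
    """A conversion-factor estimate cannot be formed (e.g. zero mean N2 rate)."""


class BudgetError(CrustfixError):
    """An N-budget cannot be computed (negative rates, missing seasons)."""


class Violation:
    """One schema or referential-integrity violation in a campaign directory."""

    __slots__ = ("file", "row", "column", "message")

    def __init__(self, file: str, row: object, column: str, message: str):
        self.file = file
        self.row = row
        self.column = column
        self.message = message

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Violation(file={self.file!r}, row={self.row!r}, column={self.column!r}, message={self.message!r})"

    def __str__(self) -> str:
        return f"{self.file}[row={self.row}, col={self.column}]: {self.message}"


class CampaignValidationError(CrustfixError):
    """Raised when a campaign directory fails validation; carries all violations."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        lines = "\n".join(f"  - {v}" for v in violations)
        super().__init__(f"campaign validation failed with {len(violations)} violation(s):\n{lines}")
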