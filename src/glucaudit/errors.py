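"""Exception hierarchy for the audit pipeline."""


class GlucauditError(Exception):
    """Base class for all package errors."""


class SchemaError(GlucauditError):
    """A CSV header does not match the expected schema."""


class RowValidationError(GlucauditError):
    """One or more rows failed domain validation.

    Carries ``problems``: a list of (row_index, message) pairs so no
    failure is silently dropped.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.problems[:20])
        extra = "" if len(self.problems) <= 20 else f" (+{len(self.problems) - 20} more)"
        super().__init__(f"{len(self.problems)} invalid row(s): {lines}{extra}")


class ConfigError(GlucauditError):
    """A configuration value is missing, malformed, or inconsistent."""


class DataIntegrityError(GlucauditError):
    """Input records violate an integrity constraint (e.g. negative latency)."""
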