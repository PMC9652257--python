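"""Exception hierarchy."""


class LiverDSSError(Exception):
    """Base class for package errors."""


class CohortSchemaError(LiverDSSError):
    """The CSV is missing a mandatory column or is structurally unreadable."""


class CohortValidationError(LiverDSSError):
    """One or more rows violate a field invariant (strict mode)."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class EmptyCohortError(LiverDSSError):
    """An operation requiring a non-empty cohort received an empty one."""


class ConfigError(LiverDSSError):
    """Invalid simulation or analysis configuration."""


class DegenerateDesignError(LiverDSSError):
    """A model matrix with fewer than two observed difficulty levels."""


class DegenerateOutcomeError(LiverDSSError):
    """An outcome vector that is constant and cannot be modelled."""
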