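"""Exception hierarchy for the erpbci package."""


class ErpBciError(Exception):
    """Base class for all erpbci errors."""


class InvalidArgumentError(ErpBciError, ValueError):
    """An argument violates an operation's precondition."""


class InvalidSpecError(ErpBciError, ValueError):
    """A paradigm specification is internally inconsistent."""


class SignalTooShortError(ErpBciError, ValueError):
    """Recording too short for the requested filter."""


class EmptyConditionError(ErpBciError, ValueError):
    """No epochs carry the requested condition label."""


class EmptyResultError(ErpBciError, ValueError):
    """An operation retained zero items (e.g. all epochs dropped)."""


class ModelGenerationFailureError(ErpBciError, RuntimeError):
    """Stepwise selection found no feature meeting the entry criterion.

    Mirrors the classifier contract: if no candidate reaches p < p_enter on
    the very first forward step, model generation fails rather than silently
    returning an empty model.
    """


class UndefinedCorrelationError(ErpBciError, ValueError):
    """Rank correlation undefined (constant input)."""
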