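"""Exception hierarchy shared across the package."""


class FiskaError(Exception):
    """Base class for all package-specific errors."""


class InputError(FiskaError, ValueError):
    """A record or argument violates a documented precondition."""


class ConfigError(FiskaError, ValueError):
    """A configuration document is missing entries or fails validation."""


class SchemaError(FiskaError, ValueError):
    """A tabular input does not match the expected column schema."""


class DomainError(FiskaError):
    """A clinically invalid operation, e.g. scoring an ABO-incompatible pair."""


class RuleBaseError(FiskaError, ValueError):
    """A rule references an unknown variable or fuzzy set."""


class NoRuleFiredError(DomainError):
    """The aggregated output membership is identically zero for an input."""

    def __init__(self, inputs=None):
        self.inputs = dict(inputs) if inputs else {}
        detail = f" for inputs {self.inputs}" if self.inputs else ""
        super().__init__(f"no rule fired{detail}; the rule base does not cover this input")


class MalformedTreeError(FiskaError):
    """A decision-tree path produced an empty value interval."""
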