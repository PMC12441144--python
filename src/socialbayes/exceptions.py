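"""Exception hierarchy for socialbayes."""


class SocialBayesError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SocialBayesError, ValueError):
    """Invalid design, model or fitting configuration."""


class DomainError(SocialBayesError, ValueError):
    """Argument outside its mathematical domain (e.g. a boundary probability)."""


class MatchingError(SocialBayesError, RuntimeError):
    """No advisor satisfies the risk-excess matching rule at any relaxation."""


class StateError(SocialBayesError, RuntimeError):
    """Operation called on an object in an invalid state (e.g. unresolved social labels)."""


class InferenceError(SocialBayesError, RuntimeError):
    """Optimisation or sampling failure."""


class ComparisonError(SocialBayesError, ValueError):
    """Model-comparison inputs are inconsistent (e.g. mismatched observation sets)."""
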