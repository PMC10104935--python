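"""Exception hierarchy shared across the toolkit.

``DomainError`` signals invalid statistical inputs (a subclass of
``ValueError`` so generic validation code keeps working), ``UsageError``
signals a malformed request such as an empty grid, ``ConfigurationError``
covers scenario-file problems, ``NumericalError`` wraps quadrature or
underflow failures, and ``CapabilityError`` marks requests that are valid
but beyond what the implementation will enumerate.
"""


class SevBayesError(Exception):
    """Base class for all toolkit errors."""


class DomainError(SevBayesError, ValueError):
    """A statistical input is outside its valid domain."""


class DegenerateHypothesisError(DomainError):
    """An interval hypothesis has zero prior mass (point hypothesis)."""


class UsageError(SevBayesError, ValueError):
    """The request itself is malformed (empty grid, bad weights, ...)."""


class ConfigurationError(SevBayesError):
    """A scenario configuration file is missing, unparseable, or invalid."""


class NumericalError(SevBayesError):
    """A numerical routine failed to converge or lost all precision."""


class CapabilityError(SevBayesError):
    """The request is valid but exceeds implemented limits."""
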