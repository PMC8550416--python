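"""Exception hierarchy shared across the package."""


class SmmbnError(Exception):
    """Base class for all package-specific errors."""


class GraphError(SmmbnError, ValueError):
    """Invalid graph construction or mutation."""


class CycleError(GraphError):
    """An operation would introduce a directed cycle."""


class IdentifierError(SmmbnError, KeyError):
    """A node or variable name is not known to the object being queried."""


class ContractError(SmmbnError, ValueError):
    """A documented precondition was violated by the caller."""


class UndefinedConditionalError(SmmbnError, ArithmeticError):
    """A conditional probability was requested against zero-probability evidence."""


class ConfigurationError(SmmbnError, ValueError):
    """Inconsistent or infeasible configuration (constraints, calibration, ...)."""


class DegenerateClassError(SmmbnError, ValueError):
    """A class-balance operation received a single-class target column."""


class DegenerateOddsError(SmmbnError, ArithmeticError):
    """An odds ratio was requested where one conditional probability is 0 or 1."""
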