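"""Exception hierarchy for cellcap."""


class CellcapError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CellcapError, ValueError):
    """An argument lies outside the mathematical domain (e.g. non-positive size)."""


class ConfigurationError(CellcapError, ValueError):
    """A law, rule or scenario configuration is invalid or incomplete."""


class UsageError(CellcapError, ValueError):
    """An operation was called outside its stated regime of validity."""


class NumericalError(CellcapError, RuntimeError):
    """A numerical routine (quadrature, root finding) failed to converge."""


class DivergenceError(CellcapError, RuntimeError):
    """A lineage failed to reach the time horizon within the generation cap."""
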