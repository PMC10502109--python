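"""Exception hierarchy for the decrem package."""


class DecremError(Exception):
    """Base class for all decrem-specific errors."""


class ParseError(DecremError):
    """A model or table file could not be parsed under the requested dialect."""


class AlignmentError(DecremError):
    """Omics blocks could not be aligned on a shared strain index."""


class BasisExtractionError(DecremError):
    """Sparse-basis LP failed in both disjunction branches for a cluster."""


class AssemblyError(DecremError):
    """Decoupled-model assembly produced an empty bound interval for an LBR."""


class InfeasibleError(DecremError):
    """An LP was infeasible or unbounded where an optimum was required."""


class ConfigurationError(DecremError):
    """Missing or inconsistent configuration (e.g. absent thermodynamic constant)."""


class MetricError(DecremError):
    """Too little shared data to compute a requested evaluation metric."""
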