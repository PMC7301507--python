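"""Exception hierarchy shared across the pipeline stages."""


class LcriskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LcriskError):
    """Invalid configuration value; the message names the offending field."""


class DomainError(LcriskError):
    """Input value outside its mathematical domain (negative counts, MAF > 0.5, ...)."""


class ConsistencyError(LcriskError):
    """Cross-table inconsistency (IDs missing from an annotation, contradictory fields)."""


class AlignmentError(LcriskError):
    """Tables that must share a subject index do not."""


class DegenerateLocusError(LcriskError):
    """A locus is monomorphic or an allele frequency sits on the boundary."""


class ZeroVarianceError(LcriskError):
    """A reference probe has zero standard deviation among never smokers."""


class DegenerateBinningError(LcriskError):
    """Quantile cut-points collapse (all control scores identical)."""


class SeparationError(LcriskError):
    """Perfect or quasi-perfect separation in a logistic fit."""


class DesignError(LcriskError):
    """Rank-deficient or otherwise unusable design matrix."""


class ClassError(LcriskError):
    """A computation requiring both outcome classes received only one."""


class FeasibilityError(LcriskError):
    """Exact enumeration would exceed the configured budget."""


class ParseError(LcriskError):
    """Malformed input file; the message cites file, line and column where possible."""


class DependencyError(LcriskError):
    """A pipeline stage requires an output another stage has not produced."""
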