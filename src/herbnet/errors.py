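"""Exception hierarchy shared across the pipeline."""


class HerbnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HerbnetError):
    """A file does not conform to its declared format (missing column,
    malformed numeric field, duplicate identifier)."""


class ValidationError(HerbnetError):
    """Inputs are well-formed but violate a semantic precondition
    (bipartite violation, inconsistent counts, infeasible config)."""


class DimensionError(ValidationError):
    """Descriptor vectors of mismatched length."""


class UndefinedSimilarityError(ValidationError):
    """Tanimoto similarity requested for two all-zero vectors; surfaced
    as an error rather than silently returning 0 so that upstream
    descriptor-computation failures are not masked."""
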