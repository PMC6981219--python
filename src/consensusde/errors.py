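"""Exception hierarchy for the pipeline.

Every reader and validator raises one of these with the offending
gene/sample named, so failures are locatable without a debugger.
"""


class ConsensusDEError(Exception):
    """Base class for all package-specific errors."""


class IdentifierError(ConsensusDEError):
    """Duplicate or unknown gene/sample identifiers."""


class DesignError(ConsensusDEError):
    """Invalid study design (wrong number of levels, undersized groups)."""


class AnnotationError(ConsensusDEError):
    """Missing or malformed gene annotation (lengths, GTF records)."""


class StructuralError(ConsensusDEError):
    """Mismatched gene universes, missing grid cells, or shape violations."""


class ConfigError(ConsensusDEError):
    """Invalid run or simulation configuration."""
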