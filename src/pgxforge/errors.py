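"""Exception hierarchy.

All toolkit errors derive from :class:`PgxForgeError` so callers can catch
one base class at the CLI boundary.
"""


class PgxForgeError(Exception):
    """Base class for all pgxforge errors."""


class ParseError(PgxForgeError):
    """A fixture or input file could not be parsed; message names the line."""


class PanelValidationError(PgxForgeError):
    """A panel, allele table or map violates one of its invariants."""


class AmbiguousTableError(PanelValidationError):
    """Two haplotypes (or two star pairs) share an identical defining vector."""


class CrossReferenceError(PanelValidationError):
    """A table references an rsid or gene absent from its panel."""


class ConfigurationError(PgxForgeError):
    """A run is missing required controls or standards."""


class DegenerateControlError(ConfigurationError):
    """A no-target control has zero intensity and cannot normalize a channel."""


class NoSignalError(PgxForgeError):
    """All readings for an assay are collapsed at the origin."""


class IncompleteDataError(PgxForgeError):
    """A sample is missing a required region or replicate."""


class InvalidRunError(PgxForgeError):
    """Run-validity standards failed; sample calls are blocked."""


class MapCoverageError(PgxForgeError):
    """A uniquely resolved diplotype is absent from the phenotype map."""


class UsageError(PgxForgeError):
    """An operation was invoked with arguments outside its contract."""
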