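"""Exception hierarchy for the screen.

Every error raised by this package derives from :class:`AlienScreenError`,
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class AlienScreenError(Exception):
    """Base class for all errors raised by alienscreen."""


class ConfigError(AlienScreenError):
    """Invalid or inconsistent run configuration."""


class InputError(AlienScreenError):
    """A required input is missing or unusable."""


class TaxonomyStructureError(AlienScreenError):
    """The taxonomy violates its structural invariants (cycle, orphan parent)."""


class UnknownTaxonError(AlienScreenError, KeyError):
    """A taxid could not be resolved in the loaded taxonomy."""

    def __init__(self, taxid):
        super().__init__(taxid)
        self.taxid = taxid

    def __str__(self) -> str:
        return f"taxid {self.taxid} is not present in the taxonomy"


class HitParseError(AlienScreenError):
    """A homology-search table could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NormalizationError(AlienScreenError):
    """No self-score available for a query, so nbs cannot be computed."""


class TreeError(AlienScreenError):
    """Malformed newick or an operation applied to an unsuitable tree."""


class RootingError(TreeError):
    """Midpoint rooting impossible (e.g. missing branch lengths)."""


class ConstraintError(TreeError):
    """A monophyly constraint cannot be built (fewer than two constrained leaves)."""


class RosterError(AlienScreenError):
    """A species label is absent from the declared species roster."""
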