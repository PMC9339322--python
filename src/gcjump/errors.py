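"""Exception hierarchy for gcjump.

All package-specific failures derive from :class:`GCJumpError` so callers can
catch one base class at pipeline boundaries.
"""


class GCJumpError(Exception):
    """Base class for all gcjump errors."""


class NewickFormatError(GCJumpError):
    """Malformed Newick input; carries the byte offset where parsing failed."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)


class PolytomyError(GCJumpError):
    """An operation that requires a binary node met a polytomy.

    Callers may resolve polytomies explicitly with
    :func:`gcjump.phylo_core.resolve_polytomies` (zero-length branches)
    before retrying; silent resolution would change contrasts and sister
    definitions, so it is never done implicitly.
    """


class TraitTableError(GCJumpError):
    """Invalid trait table: bad header, duplicate tips, out-of-range values,
    or tips that do not match the companion phylogeny."""


class OptimizationError(GCJumpError):
    """Numeric optimization failed to converge; carries best-so-far state."""

    def __init__(self, message: str, best=None):
        self.best = best
        super().__init__(message)


class EnumerationGuardError(GCJumpError):
    """Exact jump-configuration enumeration would exceed the configuration
    budget; use the Monte-Carlo marginal-likelihood estimator instead."""


class MagnitudeUnavailableError(GCJumpError):
    """Jump magnitude cannot be estimated for a call (empty affected or
    sister tip set after nested-jump exclusion)."""
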