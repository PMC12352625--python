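"""Exception hierarchy shared across hemelink modules."""


class HemelinkError(Exception):
    """Base class for all hemelink errors."""


class ParseError(HemelinkError):
    """A coordinate or table file could not be parsed; message names the offending line."""


class SiteNotFoundError(HemelinkError):
    """No haem residue (or required site atom) found where one was requested."""


class AmbiguousSiteError(HemelinkError):
    """More than one candidate haem residue on the requested chain."""


class GeometryError(HemelinkError):
    """Degenerate geometry (e.g. collinear pyrrole nitrogens)."""


class SpecError(HemelinkError):
    """A synthetic-data specification is invalid or geometrically unrealizable."""


class ValidationError(HemelinkError):
    """An input value violates a precondition (negative distance, zero frames, ...)."""


class UnsupportedPairError(HemelinkError):
    """Bond-character thresholds are not tabulated for this element pair."""


class NoSoretError(HemelinkError):
    """No transition falls inside the requested assignment window."""


class CriteriaError(HemelinkError):
    """Hydrogen-bond criteria are inconsistent with the supplied atom handles."""


class SingularityError(HemelinkError):
    """A grid point coincides with an atom position."""


class InfeasibleConstraintsError(HemelinkError):
    """The equality-constraint system admits no solution."""


class IllPosedFitError(HemelinkError):
    """The constrained least-squares system is rank deficient; message names a null direction."""
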