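"""Exception hierarchy.

Every error raised on purpose by :mod:`welltree` derives from
:class:`WellTreeError`, so callers can catch the package's failures without
masking genuine bugs.  Subclasses also derive from the matching builtin
(``ValueError``/``KeyError``) so idiomatic ``except ValueError`` still works.
"""


class WellTreeError(Exception):
    """Base class for all welltree errors."""


class InvalidArgumentError(WellTreeError, ValueError):
    """An argument violates a documented precondition."""


class ShapeError(WellTreeError, ValueError):
    """Array dimensions are inconsistent (e.g. atom-count mismatch)."""


class FormatError(WellTreeError, ValueError):
    """An input file does not parse under the declared format."""


class InsufficientDataError(WellTreeError, ValueError):
    """Too few frames/points for the requested computation."""


class DegenerateSuperpositionError(WellTreeError, ValueError):
    """Fewer than 3 non-collinear atoms: the optimal rotation is ambiguous."""


class DegenerateBreaksError(WellTreeError, ValueError):
    """Requested quantile breaks collapse (e.g. constant covariate)."""


class MissingLabelError(WellTreeError, KeyError):
    """A tree member frame has no row in the label table."""


class NodeNotFoundError(WellTreeError, KeyError):
    """Unknown tree node id."""


class TreeValidationError(WellTreeError):
    """A conformation-tree invariant is violated; the message names the node."""


class ConfigError(WellTreeError, ValueError):
    """Pipeline configuration is invalid or incomplete."""
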