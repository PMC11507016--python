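"""Exception hierarchy.

Every rejected precondition in the public API maps to a distinct subclass so
callers (and the CLI exit-code logic) can discriminate failure modes.
"""


class DupdivError(Exception):
    """Base class for all package errors."""


class GraphError(DupdivError, ValueError):
    """Invalid graph construction or mutation."""


class SelfLoopError(GraphError):
    """An edge with identical endpoints was supplied."""


class DuplicateEdgeError(GraphError):
    """The same unordered node pair was supplied twice."""


class NonPositiveWeightError(GraphError):
    """An edge weight <= 0 was supplied (weight-0 edges are not stored)."""


class UnknownNodeError(GraphError):
    """A node id that is not a member of the graph was referenced."""


class RetiredNodeError(GraphError):
    """A node id that was removed earlier in this graph's lifetime was re-added."""


class UnknownFixtureError(DupdivError, ValueError):
    """Unrecognised toy-graph fixture label."""


class EmptyGraphError(GraphError):
    """An operation that needs at least one node was called on an empty graph."""


class NoEligibleTargetError(DupdivError):
    """An attack step has no remaining eligible node or edge."""


class EnumerationTooLargeError(DupdivError):
    """Exhaustive edge-set enumeration was requested on an infeasible instance."""


class ConfigError(DupdivError, ValueError):
    """Invalid run configuration."""


class DataFormatError(DupdivError, ValueError):
    """Malformed input data file."""
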