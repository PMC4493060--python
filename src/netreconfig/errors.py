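"""Exception hierarchy for the netreconfig pipeline."""


class NetReconfigError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NetReconfigError):
    """A delimited input file violates its format contract."""


class ShapeMismatchError(NetReconfigError):
    """A matrix does not match the node table or companion matrix dimensions."""


class UndefinedMetricError(NetReconfigError):
    """A graph metric is undefined for this network (e.g. no edges, no triangles in nulls)."""


class RankDeficiencyError(NetReconfigError):
    """The confound design matrix is rank deficient."""
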