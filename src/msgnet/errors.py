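"""Exception types shared across the package."""


class MsgnetError(Exception):
    """Base class for package-specific errors."""


class UndefinedMetricError(MsgnetError, ValueError):
    """A metric has no defined value for the given input.

    Raised for example when density is requested for fewer than two
    nodes, reciprocity for an edgeless graph, or degree assortativity
    for a regular graph (zero variance).
    """


class ConvergenceError(MsgnetError, RuntimeError):
    """An iterative solver failed to converge within its iteration cap."""
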