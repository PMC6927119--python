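"""Exception types raised across the package."""


class KNMBPError(Exception):
    """Base class for all package-specific errors."""


class CycleError(KNMBPError):
    """The ontology edge table contains a directed cycle."""

    def __init__(self, edge):
        self.edge = edge
        super().__init__(f"ontology is not acyclic; cycle passes through edge {edge!r}")


class DegenerateCorpusError(KNMBPError):
    """An annotation corpus carries no information (root frequency is zero)."""


class InvalidNetworkError(KNMBPError):
    """A weighted network violates a structural precondition."""


class DegenerateInputError(KNMBPError):
    """Numerical input is degenerate (e.g. all-zero profiles for a kernel)."""
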