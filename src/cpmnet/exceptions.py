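"""Exception hierarchy for cpmnet."""


class CPMError(Exception):
    """Base class for all cpmnet errors."""


class InsufficientDataError(CPMError):
    """Too few usable frames or subjects remain for a reliable estimate."""


class DegenerateInputError(CPMError):
    """Input is structurally degenerate (e.g. single node, constant targets)."""


class ZeroVarianceError(CPMError):
    """One or more node time courses have zero variance."""

    def __init__(self, nodes):
        self.nodes = list(nodes)
        super().__init__(f"zero-variance node(s): {self.nodes}")


class InfeasibleSpecError(CPMError):
    """A synthetic cohort spec cannot be realised as a valid correlation matrix."""
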