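"""Exception hierarchy shared across the package."""


class ActSpaceError(Exception):
    """Base class for all actspace errors."""


class FormatError(ActSpaceError):
    """A file or in-memory structure does not match the expected layout."""


class InfeasibleError(ActSpaceError):
    """A constraint system has no solution.

    Attributes
    ----------
    status : int or None
        The LP solver status code backing the certificate, when available.
    prefix_len : int or None
        For stacked (trajectory) systems: the shortest prefix of time
        slices that is already infeasible, found by solving LPs on
        growing prefixes.
    """

    def __init__(self, message, status=None, prefix_len=None):
        super().__init__(message)
        self.status = status
        self.prefix_len = prefix_len


class DegenerateError(ActSpaceError):
    """The feasible set has an empty (zero-volume) relative interior."""


class GenerationError(ActSpaceError):
    """Synthetic-model generation failed after the allowed number of redraws."""


class ProvenanceError(ActSpaceError):
    """Outputs from different runs/configurations were mixed."""
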