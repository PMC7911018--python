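"""Exception hierarchy for nanograft."""


class NanograftError(Exception):
    """Base class for all nanograft errors."""


class NumberingError(NanograftError):
    """A sequence could not be assigned scheme numbering.

    Carries ``region``, the name of the first region that could not be
    anchored, when that is known.
    """

    def __init__(self, message, region=None):
        super().__init__(message)
        self.region = region


class IncompleteFrameworkError(NanograftError):
    """A framework position required for hallmark detection is missing."""


class StaleMutationError(NanograftError):
    """A mutation's expected source residue does not match the sequence."""

    def __init__(self, message, positions=()):
        super().__init__(message)
        self.positions = tuple(positions)


class DesignConflictError(NanograftError):
    """Contradictory design options target the same scheme position."""


class GraftError(NanograftError):
    """CDR grafting failed (e.g. donor loop exceeds insertion capacity)."""


class EnsembleError(NanograftError):
    """Conformations of an ensemble do not share one residue topology."""
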