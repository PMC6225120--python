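"""Exception hierarchy shared across the toolkit.

Every error raised on bad user input derives from :class:`ScarKitError`,
so callers (and the CLI) can distinguish usage problems from bugs.
"""


class ScarKitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(ScarKitError):
    """Malformed input file (illegal character, bad column, bad value)."""


class DuplicateIdError(FormatError):
    """Two records share an identifier."""


class AlignmentShapeError(ScarKitError):
    """Rows of an alignment differ in length."""


class PairingError(ScarKitError):
    """A primer table row set cannot be paired into forward/reverse pairs."""


class EmptyPanelError(ScarKitError):
    """A primer table or panel contains no usable pairs."""


class PartitionError(ScarKitError):
    """Sample sheet and sequence collection disagree."""


class DegenerateInputError(ScarKitError):
    """Too few sequences/taxa for the requested operation."""


class UndefinedDistanceError(ScarKitError):
    """No comparable sites between two aligned rows (L = 0)."""


class SaturationError(ScarKitError):
    """Substitution proportions outside the K2P domain (log argument <= 0)."""


class ConfigError(ScarKitError):
    """Invalid configuration values (panel generator, constraints, CLI)."""


class InfeasiblePanelError(ScarKitError):
    """No primer-pair combination satisfies the multiplex size-gap constraint."""

    def __init__(self, message: str, best_gap: int | None = None):
        super().__init__(message)
        self.best_gap = best_gap


class AmbiguousPanelError(ScarKitError):
    """Two panel product sizes too close to be resolved at the configured tolerance."""
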