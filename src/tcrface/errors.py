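"""Exception hierarchy: config, parse, and computation failures are distinct
so the CLI can map them to distinct exit codes."""


class TcrfaceError(Exception):
    """Base class for all package errors."""


class ParseError(TcrfaceError):
    """A structure file could not be parsed."""


class FormatError(ParseError):
    """Unknown or undeclared structure file format."""


class ConfigError(TcrfaceError):
    """Invalid configuration (roles, groupings, ranges, cutoffs)."""


class RoleAssignmentError(ConfigError):
    """Chain roles could not be assigned unambiguously."""


class SelectionError(TcrfaceError):
    """A selector matched nothing or was malformed."""


class MissingRadiusError(TcrfaceError):
    """An atom's element has no entry in the active vdW radius table."""


class PairingError(TcrfaceError):
    """Atom/residue pairing between two structures failed."""


class IncompleteResidueError(TcrfaceError):
    """A residue lacks the side-chain atoms needed for a dihedral."""


class FitError(TcrfaceError):
    """Curve fitting failed to converge."""


class ValidationError(TcrfaceError):
    """Invalid user-supplied value (sequence, position, concentration)."""
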