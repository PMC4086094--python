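"""Exception hierarchy for tspred.

All package errors derive from :class:`TspredError` so callers can catch a
single type at the CLI boundary.
"""


class TspredError(Exception):
    """Base class for all tspred errors."""


class FormatError(TspredError):
    """Malformed or unparseable input (PDB/FASTA/BIOMT records)."""


class SelectionError(TspredError):
    """A requested chain or residue does not exist in the structure."""


class BoundaryError(TspredError):
    """A sequence position is outside the admissible window range."""


class InputError(TspredError):
    """Semantically invalid input (empty sequence, non-target residue...)."""


class ConfigurationError(TspredError):
    """Degenerate parameter combination (e.g. solvation box with no waters)."""


class SolvationError(TspredError):
    """Solvation produced no bulk waters; depth is undefined."""


class ConsistencyError(TspredError):
    """Conflicting wild-type identity for the same residue position."""
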