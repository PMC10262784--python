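"""Exception hierarchy.

Every error raised by trajkit derives from :class:`TrajkitError` so callers
(and the CLI) can distinguish validation problems from runtime failures.
"""


class TrajkitError(Exception):
    """Base class for all trajkit errors."""


class PDBFormatError(TrajkitError):
    """A PDB record could not be parsed; message carries the line number."""


class TopologyMismatchError(TrajkitError):
    """Models of a multi-model PDB disagree in atom count or atom order."""


class SelectionError(TrajkitError):
    """Selection expression could not be parsed."""


class EmptySelectionError(SelectionError):
    """A syntactically valid selection matched no atoms."""


class UndefinedAngleError(TrajkitError):
    """A dihedral is undefined (missing atoms or degenerate geometry)."""


class ConfigError(TrajkitError):
    """Run configuration failed validation; message aggregates all problems."""
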