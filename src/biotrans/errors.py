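"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI: usage errors are handled by click (2),
:class:`ValidationError`/:class:`SmilesParseError`/:class:`SmirksParseError`
map to 3, :class:`IntegrityError`/:class:`PermissionDenied` to 4.
"""


class BiotransError(Exception):
    """Base class for all package errors."""


class SmilesParseError(BiotransError, ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparseable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class SmirksParseError(BiotransError, ValueError):
    """A SMIRKS string could not be parsed into a reaction transform."""

    def __init__(self, smirks: str, detail: str = ""):
        self.smirks = smirks
        msg = f"invalid SMIRKS: {smirks!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class ValidationError(BiotransError, ValueError):
    """Input fails a schema or domain constraint."""


class IntegrityError(BiotransError):
    """A referential-integrity constraint would be violated."""


class PermissionDenied(BiotransError):
    """The acting user may not perform this operation."""


class TrainingError(BiotransError):
    """A relative-reasoning model cannot be trained from the given data."""


class GenerationError(BiotransError):
    """A synthetic fixture could not be generated from its spec."""
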