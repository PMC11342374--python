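"""Exception hierarchy.

Every user-facing failure mode raises a distinct, named error so that
callers (and the command-line layer, which maps them to exit codes) can
react to the specific problem rather than parsing messages.
"""


class PeptoidsError(Exception):
    """Base class for all package errors."""


class ValidationError(PeptoidsError):
    """Invalid user input (tables, sequences, configuration)."""


class DuplicateCodeError(ValidationError):
    """Two monomer rows share the same three-letter code."""


class UnknownCategoryError(ValidationError):
    """Monomer category outside the allowed vocabulary."""


class UnknownShapeError(ValidationError):
    """Monomer shape outside the allowed vocabulary."""


class LipidCarbonError(ValidationError):
    """lipid_carbons inconsistent with the monomer category."""


class SideChainParseError(ValidationError):
    """Side-chain fragment is not valid attachment-rooted SMILES."""


class PkaError(ValidationError):
    """Malformed ionizable-group entry or pKa outside (0, 14)."""


class UnknownMonomerError(ValidationError, KeyError):
    """A monomer code does not resolve in the active monomer set."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return Exception.__str__(self)


class SequenceParseError(ValidationError):
    """A hyphen-delimited sequence string could not be parsed."""


class AssemblyError(PeptoidsError):
    """Molecule assembly failed for a named monomer."""


class InfeasiblePointError(PeptoidsError):
    """A factor point is not realizable from the given lipid pool."""


class DesignError(PeptoidsError):
    """Invalid design-of-experiments request (size, rank, candidates)."""


class FitError(PeptoidsError):
    """Response-surface fit cannot proceed (rank, rows, responses)."""
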