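"""Peptoid sequences: parsing, molecule assembly, lipid-block featurization.

Sequence strings are hyphen-delimited three-letter codes read N-terminus to
C-terminus, left to right (solid-phase synthesis proceeds C-to-N; the
display convention is chosen for readability). The assembled oligomer is
H-[N(R_i)-CH2-C(=O)]_n-NH2: a free secondary amine at the N-terminus and a
primary carboxamide at the C-terminus, the cleavage product of a Rink
amide support. No salt forms are modeled.

The lipid block of a sequence is summarized by four design factors:
number of lipid monomers, total lipid carbons, number of branched or
unsaturated ("nonlinear") lipid monomers, and the identity of the
nonlinear monomer. Featurization is order-invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from .errors import AssemblyError, SequenceParseError
from .monomers import Monomer, MonomerSet, get_monomer


@dataclass(frozen=True)
class PeptoidSequence:
    """Ordered monomer codes (N->C) resolved against a MonomerSet."""

    codes: tuple[str, ...]
    monomer_set: MonomerSet

    def __post_init__(self) -> None:
        if len(self.codes) < 1:
            raise SequenceParseError("sequence must contain at least one residue")
        for code in self.codes:
            get_monomer(self.monomer_set, code)

    def __len__(self) -> int:
        return len(self.codes)

    def residues(self) -> list[Monomer]:
        return [get_monomer(self.monomer_set, c) for c in self.codes]

    def __add__(self, other: "PeptoidSequence") -> "PeptoidSequence":
        return PeptoidSequence(self.codes + other.codes, self.monomer_set)

    def __str__(self) -> str:
        return to_string(self)


@dataclass(frozen=True)
class AssembledMolecule:
    """Full oligomer molecule with formula and masses."""

    structure: str  # canonical SMILES
    formula: str
    average_mw: float
    exact_mw: float


@dataclass(frozen=True, order=True)
class LipidBlockFactors:
    """The 4-factor parametrization of a peptoid's lipid block."""

    n_lipid_monomers: int
    total_lipid_carbons: int
    n_nonlinear: int
    nonlinear_id: str  # "none", a single monomer code, or "mixed"

    def __post_init__(self) -> None:
        if not 0 <= self.n_nonlinear <= self.n_lipid_monomers:
            raise ValueError("n_nonlinear must lie in [0, n_lipid_monomers]")
        if (self.nonlinear_id == "none") != (self.n_nonlinear == 0):
            raise ValueError("nonlinear_id is 'none' iff n_nonlinear = 0")
        if (self.total_lipid_carbons == 0) != (self.n_lipid_monomers == 0):
            raise ValueError("total_lipid_carbons = 0 iff no lipid monomers")

    def as_tuple(self) -> tuple[int, int, int, str]:
        return (self.n_lipid_monomers, self.total_lipid_carbons,
                self.n_nonlinear, self.nonlinear_id)


FACTOR_NAMES = ("n_lipid_monomers", "total_lipid_carbons",
                "n_nonlinear", "nonlinear_id")


def parse_sequence(text: str, mset: MonomerSet) -> PeptoidSequence:
    """Parse a hyphen-delimited code string against a monomer set.

    Whitespace around tokens is ignored; the error for an unknown code
    names the offending token and its 1-based position.
    """
    if text is None or not text.strip():
        raise SequenceParseError("empty sequence string")
    tokens = [t.strip() for t in text.split("-")]
    if any(not t for t in tokens):
        raise SequenceParseError(f"empty token in sequence {text!r}")
    for pos, tok in enumerate(tokens, start=1):
        if tok not in mset:
            raise SequenceParseError(
                f"unknown monomer code {tok!r} at position {pos} in {text!r}")
    return PeptoidSequence(tuple(tokens), mset)


def to_string(seq: PeptoidSequence) -> str:
    """Serialize back to the hyphen-delimited form (parse round-trips)."""
    return "-".join(seq.codes)


def assemble_molecule(seq: PeptoidSequence) -> AssembledMolecule:
    """Build the full N-substituted glycine oligomer.

    Each residue contributes the backbone unit N(R)-CH2-C(=O); the chain is
    capped with H at the N-terminus and NH2 at the C-terminus. The molecule
    is constructed as SMILES by splicing each attachment-rooted side-chain
    fragment into its backbone nitrogen branch, then canonicalized.
    """
    parts = []
    for code, mono in zip(seq.codes, seq.residues()):
        frag = mono.fragment_smiles
        if Chem.MolFromSmiles(mono.side_chain) is None:  # defensive re-check
            raise AssemblyError(f"cannot assemble monomer {code!r}: bad fragment")
        parts.append(f"N({frag})CC(=O)")
    smiles = "".join(parts) + "N"
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise AssemblyError(
            f"assembly produced invalid structure for sequence {to_string(seq)!r}")
    return AssembledMolecule(
        structure=Chem.MolToSmiles(mol),
        formula=rdMolDescriptors.CalcMolFormula(mol),
        average_mw=Descriptors.MolWt(mol),
        exact_mw=Descriptors.ExactMolWt(mol),
    )


def featurize_lipid_block(seq: PeptoidSequence) -> LipidBlockFactors:
    """Compute the 4 lipid-block design factors of a sequence.

    Counts residues of category ``lipid`` only; the headgroup and any
    hydrophilic/charged residues contribute nothing. ``nonlinear_id`` is
    the unique code among branched/unsaturated lipid residues, ``none`` if
    there are none, or ``mixed`` when more than one distinct code occurs.
    """
    lipids = [m for m in seq.residues() if m.category == "lipid"]
    nonlinear = [m for m in lipids if m.shape in ("branched", "unsaturated")]
    distinct = sorted({m.code for m in nonlinear})
    if not distinct:
        ident = "none"
    elif len(distinct) == 1:
        ident = distinct[0]
    else:
        ident = "mixed"
    return LipidBlockFactors(
        n_lipid_monomers=len(lipids),
        total_lipid_carbons=sum(m.lipid_carbons for m in lipids),
        n_nonlinear=len(nonlinear),
        nonlinear_id=ident,
    )
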