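"""Monomer dictionary: building blocks for submonomer peptoid synthesis.

A peptoid is an N-substituted glycine oligomer; each residue is defined by
the primary amine used in the displacement step of the submonomer cycle.
This module loads, validates, and serves the table of monomer
functionalities (three-letter code, category, N-substituent side chain,
lipid-carbon count, chain shape, and ionizable groups with lookup pKa
values), including a packaged default pool of 39 monomers spanning
cationic, hydrophilic, anionic, lipid, and other side chains.

Side chains are stored as attachment-rooted SMILES: the string starts with
a ``*`` dummy marking the atom bonded to the backbone nitrogen.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .errors import (
    DuplicateCodeError,
    LipidCarbonError,
    PkaError,
    SideChainParseError,
    UnknownCategoryError,
    UnknownMonomerError,
    ValidationError,
)

CATEGORIES = ("cationic", "hydrophilic", "lipid", "anionic", "other")
SHAPES = ("linear", "branched", "unsaturated", "none")

#: Exact column order of the monomer CSV interface.
CSV_COLUMNS = ("code", "name", "category", "side_chain",
               "lipid_carbons", "shape", "pka_list")


@dataclass(frozen=True)
class IonizableGroup:
    """One titratable site with a lookup acid-dissociation exponent."""

    label: str
    pka: float
    kind: str  # "base" or "acid"

    def __post_init__(self) -> None:
        if self.kind not in ("base", "acid"):
            raise PkaError(f"ionizable group kind must be base/acid, got {self.kind!r}")
        if not 0.0 < self.pka < 14.0:
            raise PkaError(f"pKa must lie in (0, 14), got {self.pka}")


@dataclass(frozen=True)
class Monomer:
    """A single submonomer building block."""

    code: str
    name: str
    category: str
    side_chain: str
    lipid_carbons: int = 0
    shape: str = "none"
    groups: tuple[IonizableGroup, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise UnknownCategoryError(
                f"monomer {self.code!r}: unknown category {self.category!r}")
        if self.shape not in SHAPES:
            from .errors import UnknownShapeError
            raise UnknownShapeError(
                f"monomer {self.code!r}: unknown shape {self.shape!r}")
        is_lipid = self.category == "lipid"
        if is_lipid and self.lipid_carbons <= 0:
            raise LipidCarbonError(
                f"lipid monomer {self.code!r} must have lipid_carbons > 0")
        if not is_lipid and self.lipid_carbons != 0:
            raise LipidCarbonError(
                f"non-lipid monomer {self.code!r} must have lipid_carbons = 0")
        if is_lipid == (self.shape == "none"):
            from .errors import UnknownShapeError
            raise UnknownShapeError(
                f"monomer {self.code!r}: shape {self.shape!r} inconsistent "
                f"with category {self.category!r}")
        _validate_side_chain(self.code, self.side_chain)

    @property
    def fragment_smiles(self) -> str:
        """Side chain with the ``*`` attachment marker stripped."""
        return self.side_chain[1:]


def _validate_side_chain(code: str, side_chain: str) -> None:
    if not side_chain.startswith("*") or len(side_chain) < 2:
        raise SideChainParseError(
            f"monomer {code!r}: side chain must be attachment-rooted SMILES "
            f"starting with '*', got {side_chain!r}")
    if side_chain.count("*") != 1:
        raise SideChainParseError(
            f"monomer {code!r}: exactly one attachment atom allowed")
    if Chem.MolFromSmiles(side_chain) is None:
        raise SideChainParseError(
            f"monomer {code!r}: unparseable side-chain fragment {side_chain!r}")


def side_chain_carbons(m: Monomer) -> int:
    """Carbon count of the side-chain fragment from its molecular graph."""
    mol = Chem.MolFromSmiles(m.side_chain)
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")


@dataclass
class MonomerSet:
    """Ordered, code-keyed collection of monomers."""

    monomers: dict[str, Monomer] = field(default_factory=dict)
    provenance: str = ""

    def add(self, m: Monomer) -> None:
        if m.code in self.monomers:
            raise DuplicateCodeError(f"duplicate monomer code {m.code!r}")
        self.monomers[m.code] = m

    def __len__(self) -> int:
        return len(self.monomers)

    def __iter__(self):
        return iter(self.monomers.values())

    def __contains__(self, code: str) -> bool:
        return code in self.monomers

    def __getitem__(self, code: str) -> Monomer:
        return get_monomer(self, code)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MonomerSet):
            return NotImplemented
        return list(self.monomers.items()) == list(other.monomers.items())

    @property
    def codes(self) -> list[str]:
        return list(self.monomers)

    def subset(self, codes: list[str], provenance: str = "subset") -> "MonomerSet":
        out = MonomerSet(provenance=provenance)
        for c in codes:
            out.add(get_monomer(self, c))
        return out


def _parse_pka_list(code: str, text: str) -> tuple[IonizableGroup, ...]:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return ()
    groups = []
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        parts = item.split(":")
        if len(parts) != 3:
            raise PkaError(
                f"monomer {code!r}: pka_list entry {item!r} is not "
                f"label:kind:value")
        label, kind, value = parts
        try:
            pka = float(value)
        except ValueError as exc:
            raise PkaError(
                f"monomer {code!r}: non-numeric pKa {value!r}") from exc
        groups.append(IonizableGroup(label=label, pka=pka, kind=kind))
    return tuple(groups)


def _format_pka_list(groups: tuple[IonizableGroup, ...]) -> str:
    return ";".join(f"{g.label}:{g.kind}:{g.pka:g}" for g in groups)


def load_monomer_table(path) -> MonomerSet:
    """Read a monomer CSV into a validated :class:`MonomerSet`.

    Row order is preserved. Each failure mode raises its own error type:
    duplicate codes, unknown category or shape, a lipid row without
    carbons, an unparseable side-chain fragment, or a malformed pKa entry.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"monomer table {path} missing columns {missing}")
    mset = MonomerSet(provenance=str(path))
    for _, row in df.iterrows():
        code = row["code"].strip()
        try:
            carbons = int(row["lipid_carbons"])
        except ValueError as exc:
            raise ValidationError(
                f"monomer {code!r}: non-integer lipid_carbons "
                f"{row['lipid_carbons']!r}") from exc
        mset.add(Monomer(
            code=code,
            name=row["name"],
            category=row["category"].strip(),
            side_chain=row["side_chain"].strip(),
            lipid_carbons=carbons,
            shape=row["shape"].strip(),
            groups=_parse_pka_list(code, row["pka_list"]),
        ))
    return mset


def write_monomer_table(mset: MonomerSet, path) -> None:
    """Write a MonomerSet as CSV; round-trips through load_monomer_table."""
    rows = [{
        "code": m.code,
        "name": m.name,
        "category": m.category,
        "side_chain": m.side_chain,
        "lipid_carbons": m.lipid_carbons,
        "shape": m.shape,
        "pka_list": _format_pka_list(m.groups),
    } for m in mset]
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def get_monomer(mset: MonomerSet, code: str) -> Monomer:
    """Exact (case-sensitive) lookup of a monomer by code."""
    try:
        return mset.monomers[code]
    except KeyError:
        raise UnknownMonomerError(f"unknown monomer code {code!r}") from None


def default_monomer_set() -> MonomerSet:
    """The packaged 39-monomer pool.

    Headgroup pKa values are literature lookup values for the free amines,
    not per-molecule predictions; every field can be overridden by loading
    a user table.
    """
    ref = importlib.resources.files("peptoids").joinpath("data/monomers.csv")
    with importlib.resources.as_file(ref) as p:
        mset = load_monomer_table(p)
    mset.provenance = "packaged default"
    return mset


#: Codes of the packaged lipid pool used for lipid-block design.
DEFAULT_LIPID_CODES = ("Hex", "Oct", "Dec", "Dod", "Ehx", "Ole")
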