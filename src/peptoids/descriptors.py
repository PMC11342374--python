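"""Physical-property descriptors for peptoid library clustering.

Seven features per peptoid drive family clustering: molecular weight,
logP, topological polar surface area, total monomer count, lipid monomer
count, total lipid carbons, and net charge at pH 5.5 (charge at pH 7.0 is
computed as an auxiliary column but excluded from the default feature
list).

Net charge uses the Henderson-Hasselbalch relation summed over
independent ionizable groups:

    q(pH) = sum_base 1 / (1 + 10^(pH - pKa))
          - sum_acid 1 / (1 + 10^(pKa - pH))

Site-site coupling is deliberately ignored; with independent sites the
sum is exact (it equals the Boltzmann-weighted microstate average).

logP (Crippen) and TPSA (Ertl) come from published atomic-contribution
schemes on the assembled structure. Absolute values differ from
proprietary predictors; clustering standardizes columns, so only the
relative ordering across the library matters.
"""

from __future__ import annotations

import pandas as pd
from rdkit.Chem import Crippen, rdMolDescriptors
from rdkit import Chem

from .errors import ValidationError
from .monomers import IonizableGroup
from .sequences import PeptoidSequence, assemble_molecule, featurize_lipid_block, to_string

#: The clustering feature set, in canonical column order.
CLUSTER_FEATURES = ("mw", "logp", "tpsa", "n_total_monomers",
                    "n_lipid_monomers", "total_lipid_carbons", "charge_ph55")

DESCRIPTOR_COLUMNS = ("mw", "logp", "tpsa", "n_total_monomers",
                      "n_lipid_monomers", "total_lipid_carbons",
                      "charge_ph55", "charge_ph7", "smiles")


def charge_at_ph(groups, ph: float) -> float:
    """Net elementary charge of a set of independent ionizable groups.

    Each base contributes its protonated fraction (+), each acid its
    deprotonated fraction (-). An empty list gives 0. A base at its own
    pKa contributes exactly +0.5.
    """
    if not 0.0 < ph < 14.0:
        raise ValidationError(f"pH must lie in (0, 14), got {ph}")
    charge = 0.0
    for g in groups:
        if g.kind == "base":
            charge += 1.0 / (1.0 + 10.0 ** (ph - g.pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (g.pka - ph))
    return charge


def ionizable_groups_of(seq: PeptoidSequence) -> list[IonizableGroup]:
    """All ionizable groups of a sequence, residue order preserved."""
    out: list[IonizableGroup] = []
    for mono in seq.residues():
        out.extend(mono.groups)
    return out


def descriptor_vector(seq: PeptoidSequence) -> dict:
    """The 7 clustering features (+ auxiliary pH-7 charge and SMILES)."""
    mol = assemble_molecule(seq)
    factors = featurize_lipid_block(seq)
    groups = ionizable_groups_of(seq)
    rd = Chem.MolFromSmiles(mol.structure)
    return {
        "mw": mol.average_mw,
        "logp": Crippen.MolLogP(rd),
        "tpsa": rdMolDescriptors.CalcTPSA(rd),
        "n_total_monomers": len(seq),
        "n_lipid_monomers": factors.n_lipid_monomers,
        "total_lipid_carbons": factors.total_lipid_carbons,
        "charge_ph55": charge_at_ph(groups, 5.5),
        "charge_ph7": charge_at_ph(groups, 7.0),
        "smiles": mol.structure,
    }


def descriptor_table(library, ids=None) -> pd.DataFrame:
    """Descriptor matrix for a library, one row per peptoid.

    Row order matches the input. Per-row failures are collected and
    reported together with their ids; no partial table is returned.
    """
    seqs = list(library)
    if not seqs:
        raise ValidationError("empty library")
    if ids is None:
        ids = list(range(1, len(seqs) + 1))
    rows, failures = [], []
    for pid, seq in zip(ids, seqs):
        try:
            rows.append({"id": pid, **descriptor_vector(seq)})
        except Exception as exc:  # noqa: BLE001 - aggregate and re-raise
            failures.append((pid, to_string(seq), str(exc)))
    if failures:
        detail = "; ".join(f"id {pid} ({s}): {msg}" for pid, s, msg in failures)
        raise ValidationError(f"descriptor computation failed for {detail}")
    return pd.DataFrame(rows, columns=["id", *DESCRIPTOR_COLUMNS])
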