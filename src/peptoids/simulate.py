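"""Synthetic peptoid libraries and synthetic in vivo screening responses.

No animal data ship with this package; this module generates screening
responses with the statistical structure the downstream analysis assumes,
so every stage is testable end to end.

Truth surface
-------------
Log10 total flux (photons/s) is a concave quadratic in the three
continuous lipid-block factors with an interior maximum, plus a
categorical effect of the nonlinear identity. The default is centered at
(6 lipid monomers, 55 total carbons, 3 nonlinear monomers) with the
branched identity (Ehx) favored over the unsaturated (Ole) — the
qualitative optimum reported for liver-directed peptoid nanoparticles —
and spans roughly four orders of magnitude over the default feasible
space. The default categorical effects are symmetric (+0.4 / -0.4 /
0 for none) so the surface lies exactly in the span of the effect-coded
quadratic model basis; all coefficients are generator configuration, not
measured values. Replicate noise is log-normal: Gaussian with sd 0.25 on
the log10 scale, echoing the ~20-40% CV of replicate flux measurements.

Organ split
-----------
Per-design liver/lung/spleen fractions come from a softmax over organ
scores linear in the headgroup pKa: high-pKa (strongly basic) headgroups
shift mass to the lung, low-pKa headgroups to the liver, mirroring the
empirical link between particle charge and lung tropism. The lung share
is non-decreasing and the liver share non-increasing in headgroup pKa.

Library generator
-----------------
``simulate_library`` draws sequences of 2-30 residues from structured
archetypes (single headgroup + lipid block, polycationic repeats,
hydrophilic-rich chains, ...) so that descriptor clustering recovers
multi-cluster structure; the default size is 221.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_space import CandidateSet, FactorPoint
from .errors import ValidationError
from .monomers import MonomerSet
from .sequences import PeptoidSequence, to_string

ORGANS = ("liver", "lung", "spleen")


@dataclass
class TruthSurface:
    """Configured generating surface for log10 total flux."""

    intercept: float = 9.3          # log10 p/s at the center
    center: tuple = (6.0, 55.0, 3.0)
    curvature: tuple = (-0.08, -0.0015, -0.15)   # per monomer^2, carbon^2, monomer^2
    effect: dict = field(default_factory=lambda: {
        "Ehx": 0.4, "Ole": -0.4, "none": 0.0})
    noise_sd: float = 0.25          # log10 units per replicate
    organ_pka_ref: float = 8.0
    organ_slope_lung: float = 1.2   # per pKa unit
    organ_slope_liver: float = -0.8

    def __post_init__(self) -> None:
        if any(c >= 0 for c in self.curvature):
            raise ValidationError(
                "curvatures must be negative (interior maximum)")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")

    def log10_flux(self, point: FactorPoint) -> float:
        x = point.as_tuple()
        val = self.intercept + self.effect[point.nonlinear_id]
        for xi, mi, ci in zip(x[:3], self.center, self.curvature):
            val += ci * (xi - mi) ** 2
        return val

    def organ_fractions(self, headgroup_pka: float) -> dict:
        z = headgroup_pka - self.organ_pka_ref
        scores = np.array([self.organ_slope_liver * z,
                           self.organ_slope_lung * z, 0.0])
        w = np.exp(scores - scores.max())
        w /= w.sum()
        return dict(zip(ORGANS, w))

    def model_coefficients(self, spec) -> pd.Series:
        """Exact expansion of the surface in a fitted model basis.

        Valid when the categorical effects are symmetric
        (effect[Ehx] = -effect[Ole], effect[none] = 0); then the surface
        lies in the span of the 14-term model and a noiseless fit must
        recover these coefficients.
        """
        if abs(self.effect["Ehx"] + self.effect["Ole"]) > 1e-12 or \
                self.effect["none"] != 0.0:
            raise ValidationError(
                "surface not representable: categorical effects must be "
                "symmetric with none = 0")
        from .doe import CONTINUOUS, FULL_TERMS
        coef = dict.fromkeys(FULL_TERMS, 0.0)
        coef["intercept"] = self.intercept
        for name, m, c in zip(CONTINUOUS, self.center, self.curvature):
            lo, hi = spec.ranges[name]
            mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
            coef["intercept"] += c * (mid - m) ** 2
            coef[name] += c * 2.0 * (mid - m) * half
            coef[f"{name}^2"] += c * half ** 2
        coef["nonlinear_id"] = self.effect["Ehx"]
        return pd.Series(coef)


def default_truth(seed: int = 0) -> TruthSurface:
    """The default truth configuration (the seed feeds only noise)."""
    return TruthSurface()


def _headgroup_pka(seq: PeptoidSequence) -> float:
    head = seq.residues()[0]
    for g in head.groups:
        if g.kind == "base":
            return g.pka
    raise ValidationError(
        f"design {to_string(seq)!r} lacks an ionizable headgroup; organ "
        f"split requires one")


def simulate_screen(truth: TruthSurface, designs: CandidateSet,
                    n_replicates: int = 3, seed: int = 0,
                    organ_split: bool = True) -> pd.DataFrame:
    """Simulate replicate flux measurements for a set of designs.

    Returns a tidy table with columns design_id, sequence, organ,
    replicate, flux (photons/s). Replicate log10 total flux is
    truth(point) + N(0, sd); organ fractions are deterministic per design
    and sum to 1. Fully reproducible from (truth config, seed).
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for did, (pt, seq) in enumerate(zip(designs.points, designs.realizations),
                                    start=1):
        mu = truth.log10_flux(pt)
        eps = rng.normal(0.0, truth.noise_sd, size=n_replicates) \
            if truth.noise_sd > 0 else np.zeros(n_replicates)
        total = 10.0 ** (mu + eps)
        fracs = (truth.organ_fractions(_headgroup_pka(seq))
                 if organ_split else {"liver": 1.0})
        for rep, t in enumerate(total, start=1):
            for organ, frac in fracs.items():
                rows.append({"design_id": did, "sequence": to_string(seq),
                             "organ": organ, "replicate": rep,
                             "flux": t * frac})
    return pd.DataFrame(rows)


def screen_summary(screen: pd.DataFrame) -> pd.DataFrame:
    """Per-design group mean and sd of total flux across replicates."""
    total = (screen.groupby(["design_id", "replicate"])["flux"]
             .sum().reset_index())
    g = total.groupby("design_id")["flux"]
    return pd.DataFrame({"design_id": g.mean().index,
                         "mean_flux": g.mean().values,
                         "sd_flux": g.std(ddof=1).fillna(0.0).values})


# -- library generation ------------------------------------------------------

#: name -> (headgroup codes, body builder description); bodies are built in
#: _build_archetype below.
ARCHETYPES = ("head_short_lipid", "head_long_lipid", "polycationic_aromatic",
              "polycationic", "hydrophilic_short", "hydrophilic_long",
              "anionic_hydrophilic", "amphiphilic_mixed")


def _build_archetype(name: str, rng: np.random.Generator) -> list[str]:
    pick = lambda opts, k=1: list(rng.choice(opts, size=k))  # noqa: E731
    if name == "head_short_lipid":
        head = pick(["Apd", "Dea", "Mor", "Imi"])[0]
        return [head] + pick(["Hex", "Oct", "Ehx"], int(rng.integers(3, 5)))
    if name == "head_long_lipid":
        head = pick(["Apd", "Dea", "Aet", "Apr"])[0]
        return [head] + pick(["Dod", "Dec", "Ole"], int(rng.integers(5, 9)))
    if name == "polycationic_aromatic":
        k = int(rng.integers(3, 6))
        body = []
        for _ in range(k):
            body += [pick(["Aet", "Apr", "Mae"])[0], "Phe"]
        return body + pick(["Dod", "Dec"], int(rng.integers(3, 6)))
    if name == "polycationic":
        k = int(rng.integers(4, 9))
        body = []
        for _ in range(k):
            body += [pick(["Aet", "Apr", "Gnd", "Dma"])[0],
                     pick(["Hye", "Sar"])[0]]
        return body
    if name == "hydrophilic_short":
        return pick(["Hye", "Hyp", "Nme", "Sar", "Dhp"],
                    int(rng.integers(2, 6)))
    if name == "hydrophilic_long":
        return pick(["Hye", "Hyp", "Nme", "Nmp", "Mpe", "Teg", "Dhp"],
                    int(rng.integers(12, 25)))
    if name == "anionic_hydrophilic":
        k = int(rng.integers(2, 6))
        body = []
        for _ in range(k):
            body += [pick(["Cme", "Cet", "Sup"])[0], pick(["Hye", "Hyp"])[0]]
        return body
    if name == "amphiphilic_mixed":
        k = int(rng.integers(3, 7))
        body = []
        for _ in range(k):
            body += [pick(["Hye", "Nme", "Ame"])[0], pick(["Hex", "Oct"])[0]]
        return body
    raise ValidationError(f"unknown archetype {name!r}")


def simulate_library(n_peptoids: int = 221, mset: MonomerSet | None = None,
                     seed: int = 0, return_archetypes: bool = False):
    """Draw a structured synthetic library of 2-30-residue peptoids.

    Sequences come from the archetype templates above (round-robin across
    archetypes, randomized composition and length within each), giving a
    library with multi-cluster descriptor structure. Returns the sequence
    list, or ``(sequences, archetype_labels)`` when asked.
    """
    if n_peptoids < 1:
        raise ValidationError("n_peptoids must be >= 1")
    if mset is None:
        from .monomers import default_monomer_set
        mset = default_monomer_set()
    rng = np.random.default_rng(seed)
    seqs, labels = [], []
    for i in range(n_peptoids):
        name = ARCHETYPES[i % len(ARCHETYPES)]
        codes = _build_archetype(name, rng)
        assert 2 <= len(codes) <= 30
        seqs.append(PeptoidSequence(tuple(codes), mset))
        labels.append(name)
    if return_archetypes:
        return seqs, labels
    return seqs
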