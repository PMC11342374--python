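"""Lipid-block design space: enumeration, feasibility, realization.

The combinatorial space of ordered lipid blocks over a pool of p monomers
with lengths in [lo, hi] has sum_{l=lo}^{hi} p^l members; for the default
6-monomer pool (Hex, Oct, Dec, Dod, Ehx, Ole) at lengths 3-6 that is
55,944 designs. Because the 4-factor featurization ignores monomer order,
feasibility of a factor point is decided over *multisets*: a point
(n, C, B, id) is feasible iff some size-n multiset from the pool has B
monomers of the single nonlinear identity ``id`` and total carbon count C.
This makes the check a bounded composition enumeration rather than a p^l
sequence scan.

Realized sequences follow a canonical rule: pick the lexicographically
smallest realizing multiset (sorted code tuple), then lay it out
palindromically (pairs placed symmetrically outward-in, odd leftovers at
the center) after the headgroup, echoing the preference for repeating or
symmetric motifs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .errors import InfeasiblePointError, ValidationError
from .monomers import Monomer, MonomerSet
from .sequences import LipidBlockFactors, PeptoidSequence, featurize_lipid_block

#: A factor point restricted to a single (or no) nonlinear identity.
FactorPoint = LipidBlockFactors


@dataclass
class LipidPool:
    """Lipid monomers available for block design, with length bounds."""

    monomers: list[Monomer]
    length_min: int = 3
    length_max: int = 6

    def __post_init__(self) -> None:
        for m in self.monomers:
            if m.category != "lipid":
                raise ValidationError(
                    f"pool member {m.code!r} is not a lipid monomer")
        codes = [m.code for m in self.monomers]
        if len(set(codes)) != len(codes):
            raise ValidationError("duplicate codes in lipid pool")
        if not 1 <= self.length_min <= self.length_max:
            raise ValidationError("require 1 <= length_min <= length_max")

    @property
    def linear(self) -> list[Monomer]:
        return sorted((m for m in self.monomers if m.shape == "linear"),
                      key=lambda m: m.code)

    @property
    def nonlinear(self) -> list[Monomer]:
        return sorted((m for m in self.monomers if m.shape != "linear"),
                      key=lambda m: m.code)

    @property
    def size(self) -> int:
        return len(self.monomers)


def default_lipid_pool(mset: MonomerSet, codes=None,
                       length_min: int = 3, length_max: int = 6) -> LipidPool:
    """The packaged 6-monomer pool (C6-C18 chains) at lengths 3-6."""
    from .monomers import DEFAULT_LIPID_CODES, get_monomer
    codes = codes or DEFAULT_LIPID_CODES
    return LipidPool([get_monomer(mset, c) for c in codes],
                     length_min=length_min, length_max=length_max)


def count_blocks(pool: LipidPool) -> int:
    """Closed-form count of ordered blocks: sum of p^l over the lengths."""
    p = pool.size
    return sum(p ** l for l in range(pool.length_min, pool.length_max + 1))


def enumerate_blocks(pool: LipidPool):
    """Lazily iterate every ordered block (tuples of codes) by length."""
    codes = [m.code for m in pool.monomers]
    for l in range(pool.length_min, pool.length_max + 1):
        yield from itertools.product(codes, repeat=l)


def _multisets(pool: LipidPool, point: FactorPoint):
    """Yield realizing multisets (sorted code tuples) for a factor point."""
    n, C, B, ident = point.as_tuple()
    if ident == "mixed":
        return  # excluded from the design candidate space
    nonlinear = {m.code: m for m in pool.nonlinear}
    if ident != "none" and ident not in nonlinear:
        return
    nl_carbons = 0 if ident == "none" else B * nonlinear[ident].lipid_carbons
    linear = pool.linear
    need = C - nl_carbons
    n_lin = n - B
    if n_lin < 0 or need < 0:
        return
    for combo in itertools.combinations_with_replacement(linear, n_lin):
        if sum(m.lipid_carbons for m in combo) == need:
            nl_part = () if ident == "none" else (ident,) * B
            yield tuple(sorted(nl_part + tuple(m.code for m in combo)))


def is_feasible(point: FactorPoint, pool: LipidPool) -> bool:
    """Whether some pool multiset realizes the factor point."""
    return next(iter(_multisets(pool, point)), None) is not None


def factor_space(pool: LipidPool) -> list[FactorPoint]:
    """All feasible factor points, sorted lexicographically.

    Computed by composition enumeration: for each block size, nonlinear
    identity, and nonlinear count, every achievable linear-carbon total is
    collected from multisets of the linear sub-pool.
    """
    points: set[tuple] = set()
    linear = pool.linear
    for n in range(pool.length_min, pool.length_max + 1):
        ids = [("none", 0)] + [(m.code, m.lipid_carbons) for m in pool.nonlinear]
        for ident, c_nl in ids:
            b_range = [0] if ident == "none" else range(1, n + 1)
            for B in b_range:
                for combo in itertools.combinations_with_replacement(
                        linear, n - B):
                    C = B * c_nl + sum(m.lipid_carbons for m in combo)
                    points.add((n, C, B, ident))
    return [FactorPoint(*t) for t in sorted(points)]


def realize_sequence(point: FactorPoint, pool: LipidPool,
                     headgroup: Monomer) -> PeptoidSequence:
    """Canonical sequence for a feasible point: headgroup + palindromic block.

    The lexicographically smallest realizing multiset is arranged
    symmetrically about the center (pairs outward-in, odd leftovers at the
    center); the headgroup is excluded from all four factors.
    """
    best = min(_multisets(pool, point), default=None)
    if best is None:
        n, C, B, ident = point.as_tuple()
        lin_max = max((m.lipid_carbons for m in pool.linear), default=0)
        raise InfeasiblePointError(
            f"point (n={n}, carbons={C}, nonlinear={B}, id={ident}) is not "
            f"realizable from pool {[m.code for m in pool.monomers]} at "
            f"lengths [{pool.length_min}, {pool.length_max}] "
            f"(max linear chain C{lin_max})")
    counts: dict[str, int] = {}
    for c in best:
        counts[c] = counts.get(c, 0) + 1
    left, middle = [], []
    for code in sorted(counts):
        left.extend([code] * (counts[code] // 2))
        if counts[code] % 2:
            middle.append(code)
    block = left + middle + left[::-1]
    # resolve against a set containing headgroup + pool members
    mset = MonomerSet(provenance="realization")
    mset.add(headgroup)
    for m in pool.monomers:
        if m.code != headgroup.code:
            mset.add(m)
    return PeptoidSequence((headgroup.code, *block), mset)


@dataclass
class CandidateSet:
    """Feasible factor points with one canonical realization each."""

    points: list[FactorPoint]
    realizations: list[PeptoidSequence]
    pool: LipidPool

    def __post_init__(self) -> None:
        for pt, seq in zip(self.points, self.realizations):
            got = featurize_lipid_block(seq)
            if got != pt:
                raise ValidationError(
                    f"realization {seq} featurizes to {got.as_tuple()}, "
                    f"expected {pt.as_tuple()}")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, indices) -> "CandidateSet":
        return CandidateSet([self.points[i] for i in indices],
                            [self.realizations[i] for i in indices],
                            self.pool)

    def to_frame(self) -> pd.DataFrame:
        from .sequences import FACTOR_NAMES, to_string
        rows = [{**dict(zip(FACTOR_NAMES, p.as_tuple())),
                 "sequence": to_string(s)}
                for p, s in zip(self.points, self.realizations)]
        return pd.DataFrame(rows)


def candidate_set(pool: LipidPool, headgroup: Monomer) -> CandidateSet:
    """Build the full feasible candidate set with canonical realizations."""
    points = factor_space(pool)
    seqs = [realize_sequence(p, pool, headgroup) for p in points]
    return CandidateSet(points, seqs, pool)
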