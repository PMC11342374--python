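# Methods

## Sequence and molecule model

A peptoid is modeled as an ordered list of three-letter monomer codes,
N-terminus first, resolved against a monomer table. The assembled
molecule is H–[N(Rᵢ)–CH₂–C(=O)]ₙ–NH₂: each residue contributes the
backbone unit C₂H₂NO plus its N-substituent fragment; the C-terminus is
a primary carboxamide (the cleavage product of a Rink-amide-type
support) and the N-terminus a free secondary amine. No salt forms,
stereochemistry, or conformation are modeled. Side chains are stored as
attachment-rooted SMILES (`*` marks the atom bonded to the backbone
nitrogen) and the oligomer is assembled by SMILES splicing, then
canonicalized with RDKit. Structure comparisons in tests use molecular
formula or canonical-SMILES equality, never raw notation strings.

The packaged 39-monomer table is a curated fixture: the 6 lipid
monomers are fully determined (Hex C6, Oct C8, Dec C10, Dod C12,
branched 2-ethylhexyl Ehx C8, unsaturated oleyl Ole C18), the named
headgroups (Aet, Apr, Mae, Dea, Apd, Nme, Nmp, …) carry literature
lookup pKa values for their dominant amine — Apd defaults to 5.6 —
and the remaining rows are plausible members of the stated categories.
Every field is user-overridable via the CSV interface; codes are
case-sensitive; non-ionizable monomers carry an empty group list rather
than a sentinel pKa. For every lipid monomer the `lipid_carbons` field
equals the carbon count of its side-chain graph (tested).

## Descriptors and charge

Seven features drive clustering: average MW (from the assembled
formula), Crippen logP, Ertl TPSA, total monomers, lipid monomers,
total lipid carbons, and net charge at pH 5.5. Charge at pH 7.0 is
computed as an auxiliary column but excluded from the default feature
list. Charge treats ionizable groups as independent sites and sums
Henderson–Hasselbalch fractions; with independent sites this equals the
Boltzmann-weighted microstate average exactly (tested against 2^k
enumeration to 1e-10). logP and TPSA come from published
atomic-contribution schemes rather than a proprietary predictor, so
absolute values differ from other stacks; clustering consumes
column-standardized features, so only relative ordering matters.

## Clustering

Ward agglomeration on the column-standardized matrix (sample, n−1,
standard deviation; constant columns dropped with a warning), cut at
K = 12 by default. The implementation delegates to
`scipy.cluster.hierarchy.linkage(method="ward")`; merge heights are on
the distance scale (two singletons merge at their Euclidean distance),
and labels — verified against an exhaustive ESS-greedy oracle on small
instances — are the tested contract, not heights. Merge ties follow
scipy's lowest-index convention. Representative selection (unstated in
typical screening reports) picks the m members nearest each family
centroid in standardized space, ties toward the lowest row id, chosen
for reproducibility.

## Design space and feasibility

Ordered lipid blocks over a pool of p monomers with lengths in
[lo, hi] number Σ p^l; the package's default bounds for the 6-monomer
pool are 3–6, giving 55,944 exactly. Because featurization is
order-invariant, feasibility of a factor point is decided over
multisets by bounded composition enumeration; identities are restricted
to a single nonlinear monomer per design (`mixed` is representable in
featurization but excluded from the candidate space). Canonical
realization picks the lexicographically smallest realizing multiset and
lays it out palindromically after the headgroup (pairs outward-in, odd
leftovers at the center); the headgroup is excluded from all four
factors. Realization is deterministic and insensitive to pool input
order.

## Model matrix and D-optimal selection

Continuous factors are affinely scaled to [−1, 1] over the candidate
range (constants recorded for reuse at prediction time); the nonlinear
identity is effect-coded (+1 Ehx, −1 Ole, 0 none). The full model has
14 named columns in fixed order. Design selection is multi-start
Fedorov exchange (default 20 starts, seeded): from a random size-n
subset, apply the single swap with the largest determinant gain until
no swap improves, using the classical rank-one delta function with
Sherman–Morrison inverse updates (verified against naive recomputation
to 1e-8 relative). A 1e-9 ridge on XᵀX stabilizes the search; the
reported criterion is ridge-free. Equal-gain ties break toward the
lowest (out-position, in-index); the exchange provably terminates since
each accepted swap strictly increases the determinant. Distinct points
only — no replicate runs. On an 8-candidate toy instance the exchange
attains the exhaustive-search optimum; on the default 298-point space a
34-run design beats the median of 200 random subsets by about five
orders of magnitude in det(XᵀX).

## Response-surface fit and optimum

OLS on the model matrix; responses from screen tables are log₁₀ of
per-replicate total flux by default (raw scale by flag). Rank
deficiency is resolved by pivoted QR: columns whose pivot falls below
1e-8 of the leading pivot are dropped deterministically and recorded
(e.g. an all-`none` design aliases the categorical column and its
interactions). Coefficient covariance is σ²(XᵀX)⁻¹ on the retained
columns. Prediction outside the fitted scaling range logs an
extrapolation warning rather than failing.

The feasible optimum is the exhaustive argmax over the finite feasible
set; prediction ties (within 1e-9 relative) resolve to the
lexicographically smallest factor point, which makes the output
invariant to enumeration order. Uncertainty is a parametric bootstrap
(default 1000 draws, seeded): coefficients are drawn from
N(β̂, Cov) via an eigendecomposition square root (the covariance may be
singular), each draw re-optimized, and per-factor mean ± SD reported;
the categorical factor is summarized by its modal identity and share.

## Synthetic screen generator

The generator defines the study conditions for every downstream test.

* **Truth surface** — log₁₀ total flux is a concave quadratic in
  (L, C, B) centered at (6, 55, 3) with curvatures (−0.08, −0.0015,
  −0.15) per squared unit, intercept 9.3, and categorical effects
  Ehx +0.4 / Ole −0.4 / none 0. These are invented calibration
  constants chosen to echo the qualitative findings the model family is
  built for — a strong second-order dependence on carbons and
  branching, a modest one on monomer count, Ehx favored over Ole, an
  interior optimum near 6 monomers / 55 carbons / ~3 branched monomers,
  and a ~4-order-of-magnitude dynamic range over the default feasible
  space. The categorical effects are symmetric by design so the surface
  lies exactly in the span of the effect-coded model basis; this is
  what makes the noiseless coefficient-recovery test exact rather than
  approximate. All coefficients are configuration, never measured
  values; the truth is config, and seeds feed only noise.
* **Noise** — replicate noise is log-normal: Gaussian with sd 0.25 on
  log₁₀ flux (~25% CV), configurable.
* **Organ split** — liver/lung/spleen fractions are a softmax over
  organ scores linear in the headgroup pKa (lung slope +1.2, liver
  slope −0.8 per pKa unit around a reference of 8.0): strongly basic
  headgroups shift mass to lung, weakly basic ones to liver, spleen in
  between. Fractions are deterministic per design and sum to 1.
* **Library** — 221 peptoids by default, drawn round-robin from 8
  archetype templates (headgroup + short/long lipid block,
  polycationic ± aromatic repeats, short/long hydrophilic chains,
  anionic-hydrophilic, amphiphilic mixed), lengths 2–30. The archetypes
  give the descriptor matrix genuine multi-family structure: Ward
  clustering at K = 12 recovers the archetype partition with adjusted
  Rand index ≈ 0.77 at the default seed.

What the generator does *not* emulate: per-animal variation beyond
log-normal replicate noise, particle physics (size, encapsulation,
zeta), inter-organ correlation, sequence-order effects, or any
mechanistic pharmacokinetics. Passing recovery tests therefore shows
that the pipeline correctly inverts its own assumed data model at
realistic noise — not that real screens obey that model.

## Problem sizes and numerical choices

Default problem sizes: 298 feasible candidate points, 34-run designs,
3 replicates (102 observations for a 14-column model), 100-repetition
recovery experiments, 1000 bootstrap draws; the full suite runs in
seconds on one core. Recovery at defaults: the fitted optimum lands
within ±1 monomer, ±6 carbons, and the correct identity of the truth
center in ≥ 90 of 100 seeded screens (98/100 at the packaged seeds);
with noise sd 1e-8 fitted coefficients match the truth expansion to
better than 1e-6.

Degenerate inputs: a constant continuous factor raises an error on the
design-selection path (the candidate range is meaningless) but is
tolerated on the fit path, where it produces a constant column that the
pivoted QR drops as aliased — mirroring how a structurally confounded
design should be reported, not silently absorbed.

## Known limitations

* Descriptor absolute values are scheme-dependent; cluster memberships
  are comparable only within one descriptor stack.
* The packaged monomer table beyond the 6 lipids and named headgroups
  is a best-effort fixture, and pKa values are lookups, not
  predictions.
* The DOE stands in a transparent, testable algorithm (Fedorov
  exchange, D-criterion) for whatever a commercial package does
  internally; only optimality properties, not bit-for-bit designs, are
  contractual. Likewise the aliased-column drop order is this package's
  own deterministic convention.
* Default block-length bounds are 3–6 (Σ_{l=3}^{6} 6^l = 55,944 ordered
  designs for the 6-monomer pool); longer blocks are supported but the
  quadratic model has only been exercised on this range.
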