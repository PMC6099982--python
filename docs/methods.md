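# Methods

## The model

`grouptension` predicts the surface tension *ST* of a liquid compound at
293.15 K (dyn/cm = mN/m) by atom-group additivity:

    ST = Σᵢ aᵢ·Aᵢ + Σⱼ bⱼ·Bⱼ + C

where *Aᵢ* is the number of occurrences of the *i*-th atom group in the
molecule, *aᵢ* its fitted contribution, *Bⱼ* the count of the *j*-th
whole-molecule special group with contribution *bⱼ*, and *C* a global
constant.  An atom group is a heavy atom characterised by its element,
formal charge, hybridization class and the multiset of its bonded
neighbours with bond orders.  The embedded parameter set has 221 entries
(one constant, 218 atom groups, 3 special groups) fitted on 1893 liquid
compounds, ionic liquids included; a salt is one record (cation + anion
components) with a single constant term.

The model is purely connectivity-based (2D).  It deliberately ignores
conformation, so it cannot represent surface-anisotropy effects of long
homologous methylene chains (correlated molecular orientation); for such
series it returns a family-average value.

## Atom-group perception

**Centres.** Every heavy atom that carries at least one hydrogen or at
least two heavy-atom neighbours yields exactly one group.  Terminal
hydrogen-free atoms — halogens, carbonyl/nitro/sulfonyl oxygens, nitrile
nitrogens, thiocarbonyl sulfur, charged terminal oxygens — are not
centres; they are encoded in the neighbour strings of the atoms bearing
them.  (The parameter table contains no central types for these atoms,
which fixes this reading: e.g. esters contribute a carbonyl-carbon group
`C sp2/CO=O` but no carbonyl-oxygen group.)

**Canonical signature grammar.** A signature is `"<atom type>/<neighbours>"`.

* Atom type: element symbol, then `(+)`/`(-)` for a central formal
  charge, then a class: `sp3`/`sp2`/`sp`/`aromatic` for C and N (sp from
  two or more π bonds, e.g. cumulated `=N=S`); `N(-)` carries no class;
  `O` is bare; sulfur is `S2` (total bond order ≤ 2) or `S4` (higher,
  covering sulfoxides through sulfates); phosphorus is `P3`/`P4` by
  σ-coordination; `Si` and `B` are bare.  Iodine is rendered `J`.
* Neighbours: hydrogens first (`H3`), then neighbour tokens grouped by
  (element, bond class) with a bond-class prefix — none for single, `:`
  aromatic, `=` double, `#` triple — and a count digit when > 1.
  Element order B < C < N < O < P < S < Si < F < Cl < Br < J; within an
  element, single < aromatic < double < triple.
* Charge marks: one `(+)` and/or `(-)` is appended at the *end* of the
  neighbour string when any neighbour carries that sign (e.g. `H2BC(-)`,
  `CPF2(-)`, `O2=O(-)`), regardless of which token the charged atom falls
  in.  This end-of-string placement is the convention that reproduces
  every printed signature; per-token placement would render some of them
  differently.
* π marks: for saturated (sp3) N, neutral O and divalent neutral S
  centres, the number of single-bonded C/N neighbours that sit in a π
  system (aromatic, or bearing a double/triple bond) is appended as
  `(pi)`/`(2pi)`.  Carbon centres never carry π marks — their
  unsaturation lives in the bond-class prefixes.

**Aromaticity convention.** Only six-membered rings consisting of C/N
that the perception toolkit marks aromatic keep aromatic flags (benzene,
pyridine, pyridinium, fused benzo rings).  Five-membered heteroaromatics
are used in Kekulé form: the thiophene sulfur becomes `S2/C2(2pi)` and
its carbons `C sp2/H=CS` / `C sp2/HC=C`, matching the published group
inventory, which contains no aromatic S/O central types.

**Imidazolium normalisation.** Chemical drawings put the imidazolium +1
on a ring nitrogen; the model places it on the C2 carbon between the two
nitrogens, whose bonds to C2 are aromatic, while the C4=C5 backbone stays
a localised double bond with single bonds to the nitrogens.  The
normaliser performs this rewrite for every five-membered aromatic N–C–N
ring with a charged ring nitrogen; it is idempotent, conserves hydrogens
and leaves pyridinium and neutral imidazole untouched.  This reproduces
the published group assignments: N1/N3 → `N aromatic/C2:C(+)`, C2 →
`C(+) aromatic/H:N2` (or `C:N2` when 2-substituted), C4/C5 →
`C sp2/H=CN`, and side-chain methylenes see a *neutral* ring nitrogen
(`C sp3/H2CN`).

**Special groups.** For pure hydrocarbons the whole-molecule term
`Alkane` (saturated) or `Unsaturated HC` (any double/triple/aromatic
bond — alkynes are included, which the source material leaves open)
counts the carbon atoms.  `(COH)n` captures the extra association of
polyols: with *n* > 1 carbon-bound hydroxy groups it contributes *B* =
*n* − 1 (the "surplus" hydroxyls beyond the first; *B* = *n* was the
other defensible reading, but *n* − 1 matches the published
occurrence-to-molecule ratio 11/10).  Any O–H on carbon counts toward
*n*, including carboxylic and phenolic OH; the source defines the rule
only through diol/triol examples.

## Validity gating

A fitted contribution is usable for prediction only when at least three
distinct training compounds contained the group.  Invalid and unknown
groups are tracked per prediction; `strict` mode raises, lenient mode
returns the numeric value flagged `is_valid=False`.  Applying this rule
to the published per-group molecule counts marks 170 of the 221 entries
valid (counting the always-valid constant), whereas the published
summary row states 165; the package reports the recomputed number and
keeps the printed one as metadata rather than reconciling them.

## Fitting and cross-validation

The contributions solve ordinary least squares on a design matrix of
group counts (one column per signature present in the training set plus
an all-ones constant column).  The normal equations AᵀA c = Aᵀy are
solved by Gauss-Seidel iteration — coordinate descent updating one
coefficient at a time — with coefficients initialised to zero,
convergence declared when the largest coefficient change in a sweep
falls below `tol` (default 1e-6 dyn/cm) and an iteration cap of 10 000
sweeps.  For a full-column-rank design the normal matrix is symmetric
positive definite and convergence is guaranteed.  A direct dense solve
exists in the test suite only, as an independent oracle.

Rank deficiency deserves a note: group-count columns obey exact
structural identities on narrow compound classes (for pure alkanes the
`Alkane` column equals the sum of the saturated-carbon columns; for
all-centre C/H/O sets the C–O bond ends counted from the carbon and the
oxygen side coincide).  A deliberate fit on such a set raises a
singularity error.  Inside cross-validation, however, a training split
may lose exactly the compounds that made a group identifiable; there the
solver runs without the rank gate, because coordinate descent on the
(always consistent) normal equations still converges to one of the
least-squares solutions — the natural behaviour of the iterative
procedure.  Held-out compounds whose groups are absent from, or invalid
in, their training split are skipped and counted.

Statistics follow the original conventions: R² is the squared Pearson
correlation of predicted versus experimental values (the coefficient of
determination is reported alongside), the average deviation is the mean
absolute residual, the standard deviation uses an N−1 denominator, and
the regression line of predicted on experimental is reported.  Training
statistics cover only compounds whose groups are all valid.  K-fold
cross-validation (default K = 10) partitions the records by a seeded
uniform random permutation, refits each training split, re-derives
validity from that split alone, and pools the held-out predictions for
Q² and S; per-fold statistics are also kept.  Pooling (rather than
averaging per-fold values) is the implemented reading of the summary
statistics.

## Synthetic data

`generate_synthetic` emulates the fitting problem at the level the
linear model sees: integer group counts (uniform in [0, 4]) for 30
groups over 300 molecules by default, responses `counts·coef + C` plus
Gaussian noise of 2.0 dyn/cm — matching the ~2 dyn/cm residual spread of
the real parameterisation — with every group present in at least three
molecules by redrawing, so validity gating never bites by construction.
It does *not* emulate: the sparsity pattern of real group counts, the
exact structural identities between columns described above,
heteroscedastic experimental error, or inter-laboratory disagreement
(real ionic-liquid measurements differ by 1.5–3 dyn/cm between sources).
Passing synthetic-recovery tests therefore demonstrates the solver and
bookkeeping, not the chemical accuracy of refitted parameters on real
data.

The curated fixture catalogue (44 molecules: alkanes through ionic
liquids, covering all 24 published ionic-liquid example groups) carries
decompositions derived by hand from the grammar above; the perception
tests treat those hand derivations as the oracle.

## Numerical and design choices

* Contributions are stored at the printed precision (2 decimals);
  predictions are reported to 2 decimals, computed at full precision.
* Signatures use ASCII `(-)` for the typographic minus of the printed
  tables.
* Tolerances: solver `tol` measures coefficient change, not residual;
  tests that compare against the direct solve tighten it to 1e-10–1e-12.
* Problem sizes in the test suite (50×8 solver-equivalence instances,
  300×30 recovery, a 37-compound CSV pipeline) are chosen so the whole
  suite runs in seconds while still exercising every code path; they are
  scaled-down stand-ins for the 1893-compound problem, whose compound
  list is not redistributed here.
* The full published training statistics (R² 0.9039 on 1833 compounds,
  Q² 0.8823, σ 1.99, S 2.16 dyn/cm) are shipped as metadata
  (`PUBLISHED_STATISTICS`); reproducing them requires the original
  compound list, which the pipeline accepts as a CSV of
  `id,smiles,st_exp` should it be available.

## Known limitations

* Only H, B, C, N, O, P, S, Si and halogens are accepted; other elements
  raise a domain error.
* Charge canonicalisation covers the imidazolium rule only; other
  tautomer/charge drawing variants are taken as drawn.
* No temperature dependence: inputs are assumed to be 293.15 K values.
* No uncertainty per prediction beyond the global deviations.
* Homologous-chain anisotropy (CMO) and polyol association scatter are
  outside the linear model; the `(COH)n` term only softens the latter.
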