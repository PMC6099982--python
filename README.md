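# grouptension

Atom-group additivity prediction of the **surface tension of organic and
ionic liquids** at 293.15 K, in dyn/cm (= mN/m), plus the least-squares
machinery that produces such parameter sets.

Surface tension drives wetting, emulsification and extraction behaviour,
and for ionic liquids it is central to their use as designer solvents —
but measuring it is finicky (temperature, purity and technique all bias
the value).  A group-additivity model gives a fast structure-only
estimate: each heavy atom of a molecule is classified by its element,
charge, hybridization and bonded neighbours into an *atom group*, and

    ST = Σᵢ aᵢ·Aᵢ + Σⱼ bⱼ·Bⱼ + C

sums the fitted contributions *aᵢ* over the group counts *Aᵢ*, adds
whole-molecule *special group* terms (*Bⱼ*: `Alkane`, `Unsaturated HC`,
`(COH)n`) and a constant *C*.  The package embeds the published
221-entry parameter table (fitted on 1893 liquids, ionic liquids
included) and implements:

* SMILES/CSV/SDF ingestion with the imidazolium charge-placement rule
  (the ring +1 moves to the C2 carbon between the nitrogens);
* canonical atom-group perception, including the charged groups of
  ionic-liquid cations and anions (salts are one record, one constant);
* prediction with validity gating — a group parameter backed by fewer
  than three training compounds is flagged and, in strict mode, refused;
* refitting: design-matrix construction, Gauss-Seidel least squares,
  R²/deviation statistics and seeded 10-fold cross-validation (Q², S),
  exposed as a statsmodels-style `GroupContributionModel` →
  `GroupContributionResults` pair;
* a synthetic-data generator for solver and cross-validation testing.

## Worked example

The classic check is anisole (methyl phenyl ether, `COc1ccccc1`):

```python
>>> from grouptension import read_smiles, decompose, predict, load_published_table
>>> table = load_published_table()
>>> vec = decompose(read_smiles("COc1ccccc1", "anisole"), table)
>>> vec.atom_group_counts
{'C sp3/H3O': 1, 'O/C2(pi)': 1, 'C aromatic/:C2O': 1, 'C aromatic/H:C2': 5}
>>> res = predict(vec, table, strict=True)
>>> round(res.st_predicted, 2)
35.23
```

The methyl carbon (`C sp3/H3O`, 3.14), the ether oxygen with one
aromatic neighbour (`O/C2(pi)`, −1.00), the substituted ring carbon
(`C aromatic/:C2O`, 3.7) and five aromatic C–H carbons
(`C aromatic/H:C2`, 1.01 each) sum with the constant 24.34 to
**35.23 dyn/cm**; the literature value is 35.7 dyn/cm.

The same from the shell, including an ionic liquid (one record, cation
dot anion):

```bash
$ cat demo.smi
COc1ccccc1 anisole
CCCCCC hexane
CCn1cc[n+](C)c1.F[P-](F)(F)(F)(F)F emim-PF6
$ grouptension predict --in demo.smi --out demo.csv
$ cat demo.csv
id,smiles,st_pred_dyn_cm,valid,unknown_groups,invalid_groups
anisole,COc1ccccc1,35.23,True,,
hexane,CCCCCC,21.9,True,,
emim-PF6,CCn1cc[n+](C)c1.F[P-](F)(F)(F)(F)F,37.98,True,,
```

Hexane is 2×(−2.28) + 4×0.20 + 6×0.22 (Alkane term) + 24.34 = 21.90
dyn/cm.  The `valid` column is the three-compound validity gate: a
molecule containing a group parameterised from fewer than three training
compounds — or a group absent from the table altogether — is marked
invalid (strict mode refuses it instead).

Refitting on your own data takes a CSV with `id,smiles,st_exp` columns:

```bash
grouptension fit --in train.csv --out table.csv --report fit.json
grouptension cv  --in train.csv --k 10 --seed 7 --out cv.json
```

`fit.json`/`cv.json` carry n, R², Q², average and N−1 standard
deviations and per-fold detail.  The published training statistics
(R² 0.9039 over 1833 of 1893 compounds, Q² 0.8823, σ 1.99 dyn/cm,
S 2.16 dyn/cm) are available as `grouptension.PUBLISHED_STATISTICS`;
reproducing them requires the original compound list, which is not
bundled.

See `docs/methods.md` for the signature grammar, the aromaticity and
imidazolium conventions, solver details and known limitations.

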