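# acpkit

Low-dimensional sequence-feature models for anticancer peptide (ACP)
classification.

Anticancer peptides are short peptides (typically 5–30 residues) that
selectively kill cancer cells. Screening candidates experimentally is slow and
expensive, so sequence-based classifiers are used to triage them: a peptide is
encoded as a numeric descriptor vector and a binary classifier separates ACPs
from other peptides. Full descriptor sets run to thousands of dimensions and
invite the curse of dimensionality; the useful signal is typically carried by
a handful of features — e.g. a 19-dimensional model, or even a 7-feature model
(`GL.gap4`, `hydrophobicity_PRAM900101.Tr2332`, `polarizability.2.residue0`,
`Pc1.C`, `Xc1.K`, `Pc2.Hydrophobicity.8`, `secondarystruct.1.residue0`), can
classify the standard 138 ACP / 206 non-ACP benchmark competitively.

`acpkit` is a toolkit for building, inspecting and applying such
low-dimensional models:

- **Twelve descriptor encoders** over the 20 standard amino acids:
  residue k-mer compositions AAC / DPC / TPC (20 / 400 / 8000-D), k-spaced pair
  composition CKSAAP (400·(kmax+1)-D), their 5-group physicochemical analogues
  GAAC / GDPC / GTPC / CKSAAGP, the 7-class conjoint triad CT (343-D),
  composition/transition/distribution descriptors CTDC / CTDT / CTDD over 13
  physicochemical properties, and pseudo / amphiphilic pseudo amino-acid
  composition PAAC / APAAC with λ sequence-order correlation terms.
  For AAC, e.g., `f(a) = N_a / N`; for CKSAAP at gap k, the frequency of
  ordered pair (a, b) with exactly k residues between them, over N−k−1
  positions.
- **A resolvable feature-naming grammar**: every column name (`GL.gap4`,
  `Xc1.K`, `polarizability.2.residue0`, …) parses back to its encoder,
  parameters and column index, so a model is just a manifest of names and can
  be recomputed for any new peptide.
- **MRMD-style feature selection**: each feature is scored by
  `|Pearson r(feature, label)| + mean distance to the other features`
  (max-relevance–max-distance), features are ranked, and the top-1 … top-d
  nested subsets are each evaluated by stratified cross-validation, giving a
  per-dimension metric curve. `select_best` picks the smallest dimension
  maximising the F-score; `knee_points` extracts the slope-point features
  whose addition jumped the curve; `iterate_reduction` repeats the loop until
  the dimension stabilises. A greedy sequential-forward selector is included
  for comparison.
- **An evaluation harness** with pooled stratified k-fold cross-validation and
  the five conventional metrics — Sn, Sp, Acc, MCC and F-score — plus RBF-SVM
  grid search over powers of two (c ∈ 2⁻⁵…2¹⁵, g ∈ 2⁻¹⁵…2³), random forest,
  and a majority-vote ensemble.
- **A synthetic benchmark generator** (138:206 class shape, lengths 5–30, a
  planted composition bias toward {K, R, L, G, C}) so every stage is testable
  without downloads, with known ground-truth informative features.

## Worked example

```python
import acpkit as ak

# a benchmark-shaped synthetic dataset with a planted composition signal
config = ak.GeneratorConfig(n_pos=138, n_neg=206, bias=2.0, seed=1)
dataset = ak.generate(config)

X = ak.encode_many(dataset, ["AAC", "GAAC", "CTDC"])   # 344 x 64
ranking = ak.rank_features(X, dataset.labels)
print(ranking.names[:5])

spec = ak.ClassifierSpec("random-forest", n_estimators=40)
curve = ak.incremental_curve(X, dataset.labels, ranking,
                             folds=5, seed=1, spec=spec)
m, chosen = ak.select_best(curve)
report = ak.cross_validate(X.subset(chosen), dataset.labels, spec,
                           folds=5, seed=1)
print(m, report.as_dict(percent=True))
```

prints

```
['charge.G1', 'solventaccess.G3', 'positivecharge', 'L', 'K']
27 {'Sn': 94.93, 'Sp': 98.06, 'Acc': 96.8, 'MCC': 93.34, 'F-score': 95.97}
```

The planted residues (K, R, L, G, C are over-represented in the positive
class) surface immediately: the top-ranked features are the positive-charge
group fraction (`charge.G1`, `positivecharge`) and the L and K compositions.
The curve peaks at 27 of 64 features, and the pooled 5-fold CV report on that
subset reads as percentages: 96.8 % of peptides correctly classified, with
sensitivity 94.93 % (ACPs found), specificity 98.06 % (non-ACPs rejected),
and an MCC of 0.93.

The same pipeline is available from the shell:

```sh
acpkit simulate --n-pos 138 --n-neg 206 --bias 2 --seed 1 \
       --out-pos pos.fasta --out-neg neg.fasta
acpkit encode --pos pos.fasta --neg neg.fasta --encoders AAC,GAAC,CTDC \
       --out features.tsv
acpkit select --table features.tsv --labels features.tsv.labels.tsv \
       --folds 5 --seed 1 --knee 0.01 --out-prefix run1
acpkit eval --table features.tsv --labels features.tsv.labels.tsv \
       --classifier rf --folds 5 --seed 1 --save-model model.joblib \
       --out report.tsv
acpkit predict --bundle model.joblib --fasta new_peptides.fasta --out preds.tsv
```

To score peptides with the shipped seven-feature model, encode with its
manifest (`acpkit.seven_feature_manifest()` or
`src/acpkit/data/acp7d.manifest`) and train on your labelled data.

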