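# Methods

This note documents the models and procedures `acpkit` implements, the
defaults it ships, and the choices made where the design was genuinely open.

## Peptide model and validation

A peptide is an identifier plus a sequence over the 20 standard amino acids
(`ACDEFGHIKLMNPQRSTVWY`). Nonstandard residues (X, B, Z, U, O, gaps) are
rejected rather than skipped or imputed: every encoder normalises by the full
residue count (N, N−1, N−k−1, …), and silently dropping residues would
corrupt those denominators. Whole records — never individual residues — can
be excluded with `drop_invalid`. Sequence I/O enforces only N ≥ 1; each
encoder enforces its own minimum (DPC needs N ≥ 2, TPC and CT N ≥ 3, CKSAAP
at gap k needs N ≥ k+2, PAAC/APAAC need N ≥ λ+1).

## Encoders

All twelve encoders are deterministic functions of the sequence with fixed,
documented column orders, and every composition-family vector (AAC, DPC, TPC,
GAAC, GDPC, GTPC, and each gap block of CKSAAP/CKSAAGP) sums to 1.

**k-mer family.** AAC/DPC/TPC are occurrence frequencies of residue k-mers
with denominators N, N−1, N−2. CKSAAP counts ordered residue pairs with
exactly k intervening residues, for k = 0…kmax, each gap block normalised by
its N−k−1 positions; gap-block values are independent of kmax, so single
features resolve with the minimal kmax (weakest length precondition). The
default kmax is 5 (2400 features); the shipped seven-feature model's
`GL.gap4` requires only kmax ≥ 4.

**Grouped family.** Residues collapse to five physicochemical groups —
aliphatic {G,A,V,L,M,I}, aromatic {F,Y,W}, positive charge {K,R,H}, negative
charge {D,E}, uncharged {S,T,C,P,N,Q} — the established convention for
grouped compositions; the k-mer computations then run over the 5-letter
alphabet.

**Conjoint triad.** The original 7-class partition {A,G,V}, {I,L,F,P},
{Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C} (by dipole and side-chain volume).
Default normalisation is the simple frequency count/(N−2); the min–max
variant ((count−min)/max over the 343 raw counts) is selectable, since both
appear in practice.

**CTD.** The 13-property set (seven hydrophobicity scales including
PRAM900101, normalised van der Waals volume, polarity, polarizability,
charge, secondary structure, solvent accessibility), each with its standard
3-group partition. Three properties are often quoted as the canonical CTD
set, but published low-dimensional ACP models name features such as
`polarizability.2.residue0` and `secondarystruct.1.residue0`, which only
exist under the 13-property convention — so that is what ships.
Distribution descriptors use the 1-based positions of the first and the
ceil(p·count)-th occurrence for p ∈ {25, 50, 75, 100} %, divided by N and
scaled ×100. A group that never occurs contributes five zeros (the
positions are undefined; zero keeps the vector total and is documented
rather than NaN).

**PAAC / APAAC.** The three classical scales (hydrophobicity, hydrophilicity,
side-chain mass) are standardised to zero mean and unit variance over the 20
residues. PAAC's θ_j averages the mean squared scale difference between
residues i and i+j; APAAC keeps hydrophobicity and hydrophilicity separate
and uses scale products. Both normalise composition and order terms by
1 + w·Σθ, so λ → 0 and w → 0 reduce exactly to AAC. Defaults λ = 8 and
w = 0.05: λ = 8 is the smallest value under which the named feature
`Pc2.Hydrophobicity.8` exists, and w = 0.05 is the classical default weight.
Both are configurable and recorded in feature resolutions, because
pseudo-composition values depend on λ and w through the shared denominator.

**Feature names.** The grammar is fixed and case-sensitive
(render ∘ parse = identity): bare k-mers (`K`, `GL`, `GLK`), `AB.gapK`,
group names (`aliphatic`, `aliphatic.aromatic`, `g1.g2.gapK`), `ctXYZ`,
`<property>.G1` / `<property>.Tr1221` / `<property>.<group>.residueP`,
`Xc1.A` / `Xc2.lambdaJ`, `Pc1.A` / `Pc2.<Property>.J`.

## Feature selection

**Ranking.** The composite score is
`|Pearson r(feature, y)| + mean Euclidean distance of the standardised
feature column to all other columns` — max relevance plus max distance, a
redundancy penalty rewarding features far from the rest. Distances between
standardised n-vectors grow as √n, which would swamp a correlation term
bounded by 1, so Euclidean distances are divided by √n; both terms are then
O(1) and weighted equally. Zero-variance features get relevance 0 by
convention (selection must be total). Alternative scorers are pluggable
(point-biserial ≡ Pearson for binary labels; ANOVA-F squashed to [0,1);
cosine and Tanimoto distances) and every ranking records which scorers
produced it. Ties break by descending score then lexicographic name, so
rankings are bit-reproducible across platforms.

**Incremental curve.** For m = 1…d, the top-m subset is evaluated by pooled
stratified k-fold CV with a fixed classifier (default: random forest) and a
fixed seed; the curve at m = d equals a direct cross-validation of the full
matrix. `select_best` returns the smallest m maximising F-score (ties to the
smaller dimension). `knee_points` returns the features added at dimensions
where the F-score rose by more than `min_gain` (F(0) defined as 0); the
default `min_gain` of 0.01 absolute F-score is a configurable convention —
what counts as a "large slope" on such charts is not standardised — and is
echoed in outputs.

**Iterated reduction.** Re-rank the currently selected subset and re-trace
the curve until the selected dimension stops shrinking, a cap (default 10
rounds) is reached, or one feature remains. An optional `top` truncation
evaluates only the top-N ranked features per round, which keeps very wide
matrices (the full twelve-encoder stack exceeds 11 000 columns) tractable;
ranking itself is computed on all columns with a chunked distance
accumulation that never materialises a d×d matrix.

**Greedy comparison.** The greedy selector is sequential forward selection on
CV F-score, stopping at the first non-improving step. Forward-by-F-score is
one of several defensible greedy schemes; it is the simplest one consistent
with producing a small subset and a score trace, and it is labelled as this
package's choice.

## Evaluation

Folds are stratified with a seeded shuffle; out-of-fold predictions are
pooled into one confusion table and the metrics computed once. Pooling (vs.
averaging per-fold metrics) reproduces single Sn/Sp/Acc/MCC/F numbers the way
comparison tables for peptide classifiers report them; per-fold reports are
attached for diagnostics, and every report is recomputable from its stored
confusion counts. Degenerate denominators: MCC = 0 and F = 0 (and P = 0)
instead of errors, so metric curves stay total over weak subsets.

F-score defaults to the F1 of the positive (ACP) class; a support-weighted
two-class average is available (`fscore="weighted"`), since published tables
where F ≈ Acc on imbalanced data suggest the weighted convention — the
toolkit provides both and asserts neither.

Classifiers: RBF SVM (standardised on training folds only, inside the CV
pipeline), random forest (default 100 trees, seeded), and a hard
majority-vote ensemble over a configurable member list — a deliberately
plain ensemble, labelled as such in outputs. SVM grid search is exhaustive
over powers of two, c ∈ 2⁻⁵…2¹⁵ and g ∈ 2⁻¹⁵…2³ with exponent step 2 (the
classic grid-search recipe); ties break toward smaller c then smaller g.

## Synthetic data

The generator emulates the standard ACP benchmark's *shape*: 138 positives
vs 206 negatives, lengths uniform on [5, 30], residues sampled
independently. The positive class mixes the uniform background with a
uniform distribution over a tilt set (default {K, R, L, G, C}, the residues
whose composition discriminates ACPs) at weight bias/(1+bias); bias = 0
makes the classes exchangeable. The ground-truth informative features are
the tilt residues' AAC columns. An optional motif mode plants a gapped
residue pair (default G…L at gap 4) in positives, giving a known CKSAAP
target.

What the generator does **not** emulate: positional structure beyond the
optional single motif, realistic ACP physicochemistry (amphipathicity,
charge clustering), length–class correlation, and sequence-similarity
redundancy (no CD-HIT-like structure). Tests passing on synthetic data
therefore demonstrate that the pipeline recovers planted composition
signals and is correctly calibrated under the null — not that any particular
accuracy will transfer to real peptide benchmarks.

## Problem sizes and numerical conventions

The shipped tests run at desk scale, chosen so the full suite completes in
minutes on a single core: selection-recovery runs use the benchmark-shaped
n = 344 with 105 features (5 planted + 100 uninformative), 5-fold CV and
40-tree forests for curve tracing; the null-calibration check uses 20
generator seeds with the default 10-fold, 100-tree protocol; the end-to-end
golden path uses 200 peptides, all twelve encoders, and top-40 truncated
iterated reduction. Encoder correctness is checked against brute-force
enumeration oracles (explicit loops over all index tuples) to 1e−12 on
random peptides of lengths 5–30.

All randomness flows through explicit integer seeds (NumPy `default_rng`,
scikit-learn `random_state`); identical seeds give bit-identical rankings,
curves, fold assignments and predictions.

## Known limitations

- The external benchmark's headline numbers (~92.7 % accuracy at 19
  dimensions) depend on that dataset and on the original ranking tool's
  undisclosed internals; this toolkit reproduces the *procedure*, not those
  exact values, and treats them as external validation.
- The MRMD composite's two terms are equally weighted; no claim is made that
  this matches any particular tool's internal weighting.
- `greedy_select` refits one CV per candidate per step (O(d²) fits); it is
  meant for the low hundreds of features.
- The selective-ensemble classifiers used in some published comparisons are
  out of scope; the vote ensemble is a plain stand-in and labelled as such.
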