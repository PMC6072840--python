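# Methods

## Problem and data contract

The package classifies short peptides (5–25 standard amino-acid residues)
as linear B-cell epitopes (BCEs) or experimentally negative peptides
(non-BCEs). Labels are a property of the input data: in curated
immunology datasets a peptide counts as positive only when two or more
independent B-cell assays agree, and as negative when two or more assays
are negative and none positive. That labeling rule is a provenance
contract of the files the user supplies (paired FASTA or a labeled TSV);
it is not computable from sequence and is not implemented here. Peptides
shorter than 5 or longer than 25 residues are excluded by the default
length filter (both bounds configurable) because they are rare outliers
in such datasets.

## Curation

**Redundancy reduction.** To keep training and evaluation sets
non-redundant, peptides with pairwise sequence identity above 70% to an
already-retained peptide are removed by greedy clustering: peptides are
sorted by length descending and each either joins the first retained
representative exceeding the threshold or becomes a new representative.
Identity is the best ungapped full-overlap alignment of the shorter
sequence against the longer, divided by the shorter length. This is a
transparent surrogate for CD-HIT-style clustering, chosen so the package
has no binary dependency; it is declared as an approximation (word-based
heuristics and gapped local identity can differ near the threshold).

**Split.** The non-redundant set is split per class at random into
benchmark (default 80%, `round(class_size × fraction)` per class) and
independent sets. Note that with exact per-class rounding an 80% split
of, e.g., 6,893 negatives gives 5,514, not the 5,485 sometimes seen in
published curations of similar data; we implement exact rounding.

**Synthetic generator.** Tests and the acceptance script use a generator
that emulates the compositional contrast of real BCE data: residues are
drawn i.i.d. from a uniform distribution over the 20 amino acids with
N, D, P, Y up-weighted by `1 + bias_strength` in positives and
A, E, L, V, M up-weighted in negatives; lengths are uniform on 5–25.
Defaults are `bias_strength = 3` (a planted signal strong enough for
high-MCC recovery) and 500 peptides per class. The generator reproduces
class-level composition bias only — it has no positional grammar, no
phylogenetic correlation between peptides, and no label noise — so
passing tests demonstrate that the pipeline recovers compositional
signal, not that it attains any particular accuracy on real epitope
data. With `bias_strength = 0` the classes share one distribution and
any classifier's expected AUC is 0.5, which the null-safety tests check.

## Descriptors

Widths and conventions are fixed contracts: AAC 20, DPC 400, CTD 147,
AAI 20 (averaged) / 160 (full), PCP 9, BPF(k) 20k.

- **DPC denominator.** Dipeptide counts (overlapping adjacent pairs) are
  divided by the peptide length N, so vectors sum to 100(N−1)/N rather
  than 100. This convention is deliberate; `denominator="N-1"` restores
  unit normalization.
- **CTD.** The seven properties (hydrophobicity, normalized van der
  Waals volume, polarity, polarizability, charge, secondary structure,
  solvent accessibility) use the canonical Dubchak three-group residue
  partitions, bundled as configuration data (`data/ctd_groups.json`)
  rather than code. Per property: C = three group percentages; T = the
  three unordered group-pair crossing rates among adjacent residues,
  normalized by N−1; D = for each group the 1-based positions of its
  first, ⌈25%⌉-th, ⌈50%⌉-th, ⌈75%⌉-th and last occurrence, each divided
  by N (×100), zeros for absent groups.
- **AAI.** Eight cluster-central AAindex indices (BLAM930101,
  BIOV880101, MAXF760101, TSAJ990101, NAKH920108, CEDJ970104,
  LIFS790101, MIYS990104) are bundled in `data/aaindex8.json`. Because
  peptides vary in length, the mapping from per-residue indices to a
  fixed vector is composition weighting: feature (index i, residue a) =
  index_i(a) × f_a/100. The 20-dim averaged mode (mean over the eight
  indices) is the model default; the encoder isolates this choice so a
  per-position alternative could be swapped in.
- **PCP.** The 0.03 offset in absolute charge per residue is used
  verbatim as a fixed centering constant. Molecular weight is the
  average-mass peptide weight (residue masses + one water) via
  Biopython, reported raw; the tree ensembles used downstream are
  scale-invariant, and the SVM/KNN pipelines standardize features, so no
  extra normalization is applied at the descriptor level.
- **BPF.** Peptides shorter than k (possible for k = 10 with curated
  minimum length 5) zero-pad the missing blocks at the inner end of the
  terminal window.

## Classifier screening

Six families (SVM, RF, ERT, GB, AB, KNN; scikit-learn estimators) can be
trained on any of the 28 registered feature sets (5 single compositions,
17 hybrids H1–H17, 6 binary-profile sets). The protocol is stratified
5-fold cross-validation repeated 10 times (library default; desk-scale
runs in the tests and acceptance script use 2 repeats — problem sizes
below). Within each repeat, a grid search picks the hyperparameter
combination maximizing mean held-out MCC; the final hyperparameters are
the per-parameter median (mode for categoricals) of the per-repeat
winners, and aggregate performance is the mean over all folds and
repeats. Default grids are deliberately compact (tree counts 100/200,
GB learning rate 0.05/0.1, SVM C ∈ {0.1, 1, 10}, KNN k ∈ {5, 15}) and
overridable; original published search spaces for this family of methods
are not reproduced here. SVM and KNN get feature standardization in a
pipeline; tree ensembles run on raw descriptors. All randomness flows
from a single master seed (fold seeds per repeat, then a model seed).

## Ensemble and cutoff

EM1 fuses ERT-on-H7 and GB-on-H15 by an unweighted mean of predicted
probabilities; a peptide is called positive when the mean is at or above
the cutoff (`≥`, not `>`, so printed two-decimal cutoffs behave
predictably at the boundary). Both members receive the same master seed,
which makes their fold partitions coincide, so member out-of-fold
probabilities can be averaged sample-wise into ensemble out-of-fold
probabilities. The cutoff is grid-searched in steps of 0.01 over
(0, 1) to maximize MCC on those pooled out-of-fold probabilities —
out-of-fold rather than resubstitution scores, to avoid optimistic bias
in the cutoff; ties break toward the smallest cutoff. Other member
combinations (adding RF, SVM, AB, KNN) are constructible through the
same `build_ensemble` API.

## Evaluation and comparison

Sn, Sp, Acc and MCC follow the standard confusion-matrix definitions
with positive calls at `probability ≥ cutoff`; MCC returns 0 when any
denominator factor vanishes (the formula is undefined there). AUC uses
the rank-sum (Mann–Whitney) equivalence, ties counting one half.
McNemar's test on paired classifiers uses the continuity-corrected
chi-square statistic `(|b−c|−1)²/(b+c)` with an exact two-sided binomial
p-value when discordant pairs number fewer than 25; zero discordant
pairs returns p = 1 with a degeneracy warning. Compositional contrasts
use Welch's unequal-variance t-test (two-sided). The per-position
enrichment statistic compares 0/1 residue-occurrence indicators between
classes with a two-sample t-test — on binary indicators this is
equivalent to a two-proportion comparison; positions beyond a peptide's
length are skipped with counts adjusted, and C-terminal position j
counts from the last residue. No multiple-testing correction is applied
by default (raw p ≤ 0.05), with a Benjamini–Hochberg option.

## Prediction modes

Peptide mode scores each input and calls it at the model cutoff;
encoding failures (e.g. single-residue input for dipeptide features)
yield per-record error entries without stopping the run, and lengths
outside the trained 5–25 range trigger a warning. Protein scanning is an
exhaustive multi-length sliding window (defaults 12–25, the typical
linear-epitope length range; stride 1), scoring each window exactly as a
peptide; windows containing non-standard residues (X etc.) are skipped
and counted. Hits at or above the cutoff are reported in 1-based
inclusive coordinates, sorted by probability; an optional greedy merge
keeps the highest-probability member of each overlapping cluster. The
window scheme is this package's design — peptide-level scoring does not
itself prescribe a mining strategy.

## Problem sizes and numerical choices

Test-suite and acceptance-script runs use 500 peptides per class
(bias 3), 5 folds × 2 repeats for ensemble builds, and 250 per class for
null controls; these sizes give stable MCC estimates on the synthetic
task while keeping full runs in the minutes range on one CPU. The
cutoff grid step is 0.01. Grid-search ties break to the first
combination in iteration order; cutoff ties to the smallest value.
Degenerate inputs (constant probabilities, single-class labels, empty
groups) raise or warn explicitly rather than returning silent values.

## Known limitations

- The redundancy-reduction identity is an ungapped surrogate, not a
  re-implementation of word-indexed clustering tools.
- The bundled AAindex values and CTD partitions are configuration data;
  swapping them changes AAI/CTD features and any downstream model.
- Synthetic benchmarks measure signal recovery, not real-world accuracy;
  no claim about performance on externally curated epitope data is made
  or tested here.
- Published headline figures for ensembles of this design (benchmark MCC
  ≈ 0.45, AUC ≈ 0.78 on large curated datasets) require those datasets,
  which must be obtained separately; they serve only as context for
  users, not as targets the test suite reproduces.
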