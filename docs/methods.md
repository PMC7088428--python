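# Methods

This note records the model, the fixed conventions behind each feature
block, the tunable parameters with their defaults, what the synthetic data
generator does and does not emulate, and the numerical choices that matter
for reproducibility.

## Problem and model

Proteins are assigned to one of four mitochondrial compartments (inner
membrane, intermembrane space, matrix, outer membrane) from sequence-derived
features. The classifier is a multi-class support vector machine with a
Gaussian RBF kernel (one-vs-one decomposition for classification,
one-vs-rest decision values for ROC), operating on a fixed 239-dimensional
encoding. The approach assumes compartments differ in global sequence
composition and coarse structural character — it uses no alignments,
profiles, signal-peptide models or homology information, so it also applies
to proteins without detectable targeting peptides.

## Dataset curation

Intended for localization-annotated database exports. Filters run in a
fixed order, and each removed record is charged to the first filter it
fails:

1. **Ambiguous annotation** — case-insensitive substring match of the
   hedging keywords `possible`, `probable`, `by similarity`, `potential`
   against the record's free-text annotation.
2. **Multiple locations** — the annotation names more than one of the four
   compartments (keyword co-occurrence; annotated databases give no
   machine-readable multi-location flag, so this is a convention).
3. **Length** — sequences shorter than 80 residues are dropped.
4. **Alphabet** — any residue outside the 20 standard amino acids
   (`X`, `B`, `Z`, …) drops the record.

Taxonomic screening (e.g. restricting to non-plant eukaryotes) cannot be
done from FASTA and is deliberately the caller's responsibility.

**Redundancy reduction** caps pairwise identity at 70% with a greedy
longest-first clustering (the CD-HIT strategy, reimplemented so the package
has no binary dependency): records are visited longest-first (ties by id),
each joins the first representative it exceeds the threshold with, else
becomes a representative. Identity is global-alignment matches divided by
alignment columns, scored match = 1, mismatch = 0, linear gap = −1
(Biopython `PairwiseAligner`). This is deterministic and exactly testable
by exhaustive pairwise alignment; it is not claimed to reproduce CD-HIT's
word-filter heuristics cluster-for-cluster.

## Secondary-structure assignment

A self-contained Chou–Fasman propensity assignment supplies the structural
context for the `fg_sse` block. Per residue, helix and sheet propensities
are averaged over a centred window (default 5, truncated at the termini so
no fictitious residues are invented); the state is helix when the helix
average reaches the classical former cutoff 1.03 and exceeds the sheet
average, strand when the sheet average reaches 1.05 and exceeds the helix
average, coil otherwise. Both cutoffs and the propensity table
(`data/chou_fasman.tsv`) are configurable, and a precomputed H/E/C string
from any external predictor can be substituted. Propensity assignment is a
coarse approximation of real secondary structure; the SSE-derived features
are therefore convention-dependent and should be interpreted as smoothed
propensity summaries, not as predicted structure.

## Feature encoding (239 = 60 + 60 + 88 + 31)

Residue order is alphabetical one-letter (`A,C,D,…,Y`) everywhere.

- **CCD (60).** For each residue type: composition n_a/L; centroid = mean
  1-based occurrence position / L (0 when absent); distribution =
  population standard deviation of the normalized occurrence positions
  (0 when the residue occurs ≤ 1 time). These are the simplest definitions
  consistent with the three names; centroid/distribution capture positional
  bias that plain composition misses.
- **SAAC (60).** Split points floor(L/3) and floor(2L/3); each third
  contributes its own 20-composition. Captures N-/C-terminal compositional
  asymmetry (e.g. targeting-region bias) cheaply.
- **fg_sse (88) = 17 + 5 + 3 + 51 + 12.** This decomposition is a fixed
  package convention chosen to satisfy the published sub-counts (17 group
  frequencies, 5 short-peptide classes, 3 SSE contents, per-state
  features, total 88); it is not claimed to match any prior implementation
  byte-for-byte.
  - 17 global group frequencies: 10 functional groups (aliphatic AVLIG,
    hydroxyl ST, sulfur CM, aromatic FWY, basic KRH, acidic DE, amide NQ,
    imino P, tiny AG, charged DEKRH) and 7 physico-chemical groups
    (hydrophobic, hydrophilic, neutral, polar, non-polar, small, aromatic),
    all shipped in `data/groups.tsv`, never hard-coded. Groups may overlap,
    so these 17 frequencies are not constrained to sum to 1.
  - 5 short-peptide class frequencies: a length-10 window slides over the
    sequence; each window is classified by strict majority (> 5 of 10
    residues) into one of five *disjoint* residue classes — hydrophobic
    FILMVW, hydrophilic (charged) DEKR, neutral GH, polar CNQSTY,
    non-polar AP — with ties and sub-majority windows left unclassified.
    The classes are a partition by design: with overlapping classes the
    strict-majority rule would tie systematically (a window of pure
    hydrophobic residues would also be majority non-polar), leaving most
    windows unclassified.
  - 3 SSE content fractions (H, E, C).
  - 51 per-state group frequencies: each of the 17 groups within each SSE
    state, normalized by the number of residues in that state (0 when the
    state is absent — an explicit convention, not a smoothing).
  - 12 per-state short-peptide frequencies: the hydrophobic, hydrophilic,
    polar and non-polar window classes per state. A window carries the
    state of its central residue (offset 4 of 10, the N-terminal of the
    two middle positions), and frequencies are normalized by the number of
    windows centred in that state, mirroring the per-state group
    convention.
- **physchem (31).** The mean over the sequence of each of 31 per-residue
  scales (`data/physchem_scales.tsv`): hydrophobicity/hydrophilicity
  (Kyte–Doolittle, Hopp–Woods, Eisenberg, Fauchère–Pliska, Janin,
  transmembrane tendency), size and shape (bulkiness, volume, mass,
  accessible surface, Charton steric), polarity and charge (Grantham,
  Zimmerman, net charge, isoelectric point, side-chain pKa), flexibility,
  mutability, refractivity, heat capacity, Chou–Fasman propensities, and
  atomic-composition counts. The exact set is a curated convention and
  fully overridable; analyses that depend on a specific published scale
  set should supply their own table.

All frequency-type features lie in [0, 1]; every 20-long composition block
sums to 1. Encoding is a pure function of (sequence, scheme, scales,
configuration).

## Feature selection

Information gain in bits: each column is discretized into 10 equal-width
bins over its observed range (a constant column collapses to a single bin
and scores 0), then IG = H(Y) − H(Y|X). Ranking is descending with
ascending column index breaking ties, so top-k subsets are nested and
deterministic. Ranking must only ever see training data; cross-validation
re-ranks inside every training fold and applies the fold's frozen top-k to
its held-out split, so selection cannot leak test labels. Equal-width
binning is the simple, deterministic default; the bin count is a
parameter.

## Classifier and evaluation protocol

- Min–max scaling of every feature to [0, 1] using training-fold statistics
  only (constant features map to 0). RBF kernels require comparable feature
  scales; the scaling parameters are frozen into the trained model.
- Grid search over C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} × γ ∈ {2⁻¹⁵, …, 2³}
  (the libsvm-guide grid, overridable), maximizing mean stratified k-fold
  CV accuracy; ties prefer smaller C, then smaller γ — a deterministic
  preference for the smoother model.
- Class weighting is off by default (`balanced` available): real
  compartment datasets are heavily imbalanced, and unweighted training
  reflects the common practice for this kind of predictor.
- Stratified folds with seeded shuffling; fold assignment depends only on
  (labels, folds, seed). Each sample is tested exactly once per CV pass and
  the per-fold confusion matrices sum to the aggregate.
- Metrics are one-vs-rest per class. A metric whose denominator is zero
  (e.g. a fold without positives of a rare class) is reported as NaN and
  excluded from macro averages, never silently coerced to 0. AUC uses the
  rank-based Mann–Whitney formulation (ties count half), equivalent to
  trapezoidal integration of the empirical ROC; macro AUC is the unweighted
  mean of the per-class one-vs-rest AUCs computed from SVM decision values.

## Synthetic data generator

Each class emits residues i.i.d. from a 20-simplex profile; lengths are
uniform on [80, 300] by default. Every class owns a disjoint set of five
signature residues whose emission weight is multiplied by
(1 + effect_size) before normalization: effect_size 0 makes all classes
identically uniform (a permutation null for the entire pipeline), and the
default effect_size 4 boosts signatures fivefold — strong compositional
separation. An optional terminal-bias mode applies the signature profile
only to the N-terminal third, specifically exercising the SAAC and
centroid features.

What passing tests on this generator show: the pipeline recovers class
structure that is expressed in residue composition, and reports chance-level
accuracy when none exists. What they do not show: performance on real
proteins, whose compartment signal involves positional motifs, domains,
transmembrane architecture and phylogenetic correlation that an i.i.d.
emission model does not contain. Published benchmark figures on curated
database sets are therefore not comparable to numbers obtained on this
generator.

## Problem sizes and defaults

End-to-end evaluations (tests and the acceptance script) use 100 sequences
per class (400 total), lengths 80–300, 10-fold CV, in-fold top-200
selection, and a 4×4 log2-spaced C×γ grid spanning the interior of the
libsvm default ranges — a grid search proportionate to a 400-sample
dataset; the full default grid remains available and gives the same
selections on this data. Under these conditions the strong-effect pipeline
reaches ≥ 0.90 CV accuracy and the null stays near 0.25.

## Known limitations

- The fg_sse decomposition, group memberships, peptide-class partition,
  31-scale set and Chou–Fasman assignment are documented conventions;
  alternative conventions will change feature values (all are overridable
  via the TSV resources).
- The redundancy reducer is O(n²) alignments in the worst case — fine for
  curated training sets (thousands of sequences), not for whole-database
  screening.
- No probability calibration; decision values are suitable for ranking and
  ROC, not as posterior probabilities.
- Only the four-compartment problem is modelled; dual-localized proteins
  are excluded by curation rather than predicted.
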