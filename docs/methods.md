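# Methods

## The prediction problem

Given a protein and an RNA, decide whether they form a physical interaction
pair. The classifier operates on pairs of *sequences plus 1-D structure
strings*: a protein-block string describing local backbone conformation for
the protein, and a per-nucleotide secondary-structure element annotation for
the RNA. Structure-prediction tools are deliberately outside the package —
users supply protein-block strings (from a structure, or a PB predictor) and
dot-bracket secondary structures (e.g. RNAfold output); the package derives
everything downstream.

## Training-pair construction from complexes

Co-complex (protein chain, RNA chain) pairs are labelled by an atomic
contact criterion: a pair is **positive** when the minimum distance over all
(protein atom, RNA atom) pairs is ≤ 3.40 Å, **negative** otherwise. The
3.40 Å threshold covers strong/moderate hydrogen bonds and energy-rich
van der Waals contacts; the boundary is inclusive. All atoms present in the
file participate (hydrogens included when deposited); residues without
coordinates contribute no atoms but stay in the sequence, since sequence
features and contact labeling have different completeness needs. Only the
first alternate location is kept — a single conformer suffices for a
≤/> 3.40 Å decision.

Homologous pairs are collapsed: two pairs are redundant when the protein
identity **and** the RNA identity are both ≥ 30% (the *and* reading is the
one consistent with the canonical four-chain example, where two
protein-distinct pairs sharing an identical RNA are both retained).
Identity is global-alignment percent identity over the alignment length,
computed with EMBOSS-needle default scoring (BLOSUM62 / NUC.4.4, gap open
10, extend 0.5, free end gaps). Redundancy classes are connected components
of the pairwise redundancy graph; the lexicographically smallest
(complex id, protein chain, RNA chain) key represents each class, which
makes the output deterministic. Peptides (< 25 aa) and small RNAs (< 15 nt)
are excluded after labeling.

For interaction lists without experimental negatives, negatives are
generated by keeping the RNA column fixed and permuting the protein column.
The permutation is seeded; colliding rows (shuffled pair equals a known
positive) are repaired by pairwise swaps, falling back to a full redraw if a
repair pass stalls. This preserves the protein multiset and the RNA column
exactly, is deterministic per seed, and keeps distinct seeds on distinct
permutation streams (a naive "retry with seed+1" scheme makes adjacent
seeds share streams). Infeasible inputs — an RNA positive with every
protein — are detected and rejected up front.

## Feature encoding

* Protein: the 20 amino acids reduce to 7 groups by dipole moment and
  side-chain volume — {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K},
  {D,E}, {C}. Crossing groups with the 16 protein-block letters gives
  7 × 16 = 112 cells; the feature value is the normalized frequency of each
  (group, PB) co-occurrence.
* RNA: nucleotides {A,U,C,G} crossed with the five secondary-structure
  element classes {S,H,L,B,I} give 4 × 5 = 20 cells, normalized the same
  way.
* The pair vector is the concatenation, protein part first: 132 entries.

Positions with an unknown residue (X/N) or an unassigned structure code (Z)
are excluded from both numerator and denominator, so frequencies are over
observed combinations; a chain with no countable position encodes as a zero
vector rather than an error. The index layout (group-major protein cells,
PB letters ranked a–p; nucleotide-major RNA cells, classes ranked S,H,L,B,I)
is arbitrary but frozen: a saved model embeds a fingerprint of the layout
and refuses to score vectors laid out differently.

## Secondary-structure element classes

Dot-bracket strings are parsed with the standard stack algorithm; only
nested structures are supported — pseudo-knot bracket alphabets are
rejected, since crossing topologies are outside the model. Paired positions
are S. Each unpaired position is classified by the loop that owns it in the
nesting tree, following the standard loop taxonomy: hairpin interiors → H;
an unpaired run between two consecutively nested helices on one side
only → B; runs on both sides → I; multibranch interiors and the exterior
loop → L. L is the residual bucket because stems, hairpins, bulges and
internal loops are unambiguous and exactly five classes exist. By
construction #S = 2 × #pairs, and every position receives exactly one
class. Any provided base pair counts as pairing — the classifier does not
distinguish canonical from non-canonical pairs.

## Protein blocks

The 16 protein blocks are canonical five-residue backbone fragments, each
defined by eight dihedrals (ψ(i−2), φ(i−1), ψ(i−1), φ(i), ψ(i), φ(i+1),
ψ(i+1), φ(i+2)). A residue is assigned the letter of the prototype nearest
in root-mean-square angular deviation (differences wrapped to ±180°). The
first and last two residues of a chain, and any window touching a missing
dihedral, are Z (unassigned) and are skipped by the encoder. The prototype
dihedral table is vendored as a package constant from the structural
alphabet literature. Assignment is exact-match idempotent: a window set to
a prototype's dihedrals recovers that letter. Most users will instead
supply externally produced PB strings; the assignment routine exists so
experimentally solved structures can be encoded without external tools.

## Classifier

A soft-margin SVM with the polynomial kernel
K(u, v) = (γ⟨u, v⟩ + c₀)^d and the tuned hyperparameters C = 1000, γ = 1,
c₀ = 1, d = 4 (defaults of `SVMParams`). Features are already frequencies
in [0, 1], so no additional scaling is applied. The hard label is positive
iff the decision score is > 0; an exactly zero score is called negative so
ties break deterministically. Class-imbalance weighting is available but
off by default. Probability calibration is not used; ROC ranking uses raw
decision values. The dual solver is deterministic given input order; solver
tolerance and shrinking follow the underlying library defaults and are
stored with the model.

The `RpiModel` / `RpiResults` pair presents this as a fitted-model API:
`RpiModel(X, y, params).fit()` returns results carrying the trained SVM,
training diagnostics and (on request) cross-validation metrics, with a
`summary()` table; `RpiModel.from_dataframe` encodes a sequence-level pair
table on the fly.

## Evaluation

Precision = tp/(tp+fp), Recall = tp/(tp+fn), F-measure = harmonic mean,
Accuracy = (tp+tn)/total × 100. Zero-denominator ratios are reported as
undefined (None), never as 0. AUC is the rank-based Mann–Whitney statistic
with tied scores counted ½.

Cross-validation is stratified 10-fold with a required, logged seed:
stratification prevents degenerate single-class training splits on small
data, which a plain equal-size split permits. Headline metrics pool
out-of-fold confusion counts and decision scores (micro-average); a
per-fold breakdown is attached because a plain "average over folds" is
ambiguous between the two conventions.

## Synthetic data

`make_toy_complex` builds straight-line pseudo-backbones (one atom per
residue) with one designated atom pair placed at an exact target
separation — only the distance contract is physically meaningful.
`make_four_chain_complex` arranges four protein and two RNA chains with
duplicated sequences (A≡C, B≡D, Q≡R) and contacts placed so that B–Q is
positive (3.2 Å) and A–Q negative (4.5 Å), reproducing the canonical
redundancy-removal worked example end to end from PDB text.

`make_classified_pairs` draws per-pair feature compositions from
class-conditional Dirichlet distributions sharing a base concentration;
`separation` scales an antisymmetric log-concentration perturbation over a
seeded ±1 cell mask, so separation 0 makes the two classes identically
distributed and separation ≈ 6 concentrates them on complementary cells
(concentration ratio e⁶ ≈ 400, effectively disjoint supports). Sequences
realise each composition with one representative amino acid per group, so
the encoder recovers the intended cell frequencies exactly up to multinomial
noise. Defaults (200 pairs, 100-residue proteins, 50-nt RNAs, balanced
classes) are realistic chain lengths at a size where 10-fold CV is
well-conditioned.

What the generator does *not* emulate: real sequence composition and
autocorrelation, structurally consistent RSS strings (structure letters are
sampled per cell, not derived from a folded molecule), homology between
pairs, and class imbalance. Passing tests therefore demonstrate the
correctness of the machinery — encoding, training, validation, network
assembly — under controlled class-separation conditions, not predictive
accuracy on biological data, which depends on the training corpus and on
upstream structure predictions.

## Numerical choices and degenerate inputs

* Distance minima are exact (`scipy` pairwise distances); no cutoff
  heuristics.
* Angular RMSD wraps differences into [−180°, 180°] before averaging.
* A chain with zero atoms has undefined distance; such pairs are excluded
  from dataset construction rather than guessed.
* Empty feature denominators yield zero vectors; empty confusion tables and
  single-class AUC inputs raise errors.
* Model persistence is by serialization of the fitted state; reloaded
  models produce bit-identical decision scores, and a layout-fingerprint
  check rejects models saved under a different feature ordering.

## Known limitations

* Pseudo-knotted RNAs cannot be represented; their crossing pairs are
  rejected at parse time.
* The redundancy graph uses connected components, so long similarity chains
  can collapse pairs that are pairwise dissimilar at the ends.
* PB assignment requires φ/ψ series; it does not compute dihedrals from
  raw coordinates for chains with missing backbone atoms.
* mmCIF input, assembly expansion and DNA/hybrid chains are unsupported;
  DNA chains are flagged and excluded from pairing.
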