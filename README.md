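# rpipred

Sequence + structure prediction of RNA–protein interaction pairs.

RNA-binding proteins and non-coding RNAs mediate splicing, transport,
stabilization and translational control, but experimentally mapping which
protein binds which RNA is slow and expensive. `rpipred` is a supervised
predictor for this problem aimed at computational biologists who have
sequences and (predicted or experimental) structures and want ranked
interaction calls and interaction networks.

## Model

A (protein, RNA) pair is encoded as a 132-dimensional vector of normalized
frequencies:

* **Protein (112 = 7 × 16):** each residue maps to one of 7 amino-acid
  groups (by dipole moment and side-chain volume: {A,G,V}, {I,L,F,P},
  {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}) and carries one of 16
  protein-block letters (a–p), a structural alphabet of five-residue
  backbone fragments. Features are the frequencies of (group, PB) cells.
* **RNA (20 = 4 × 5):** each nucleotide (A,U,C,G) carries one of five
  secondary-structure element classes — Stem, Hairpin, Loop, Bulge,
  Internal loop — derived from a nested dot-bracket structure by standard
  loop decomposition. Features are (nucleotide, class) frequencies.

Pairs are classified by a soft-margin SVM with polynomial kernel
K(u,v) = (γ⟨u,v⟩ + c₀)ᵈ at C = 1000, γ = 1, c₀ = 1, d = 4. Training pairs
are labelled from 3-D complexes by an atomic-contact criterion: positive
iff some protein atom lies within 3.40 Å of some RNA atom. Homologous
pairs (protein **and** RNA identity ≥ 30%, EMBOSS-needle scoring) are
collapsed; peptides (< 25 aa) and small RNAs (< 15 nt) are excluded.
Performance is measured by Precision, Recall, F-measure, Accuracy and
rank-based AUC under stratified 10-fold cross-validation, and predictions
can be exported as bipartite protein–RNA networks (SIF/GraphML/TSV).

## Worked example

```python
from rpipred import (FixtureSpec, RpiModel, make_classified_pairs)

# synthetic pair table with class-separated compositions
table, _ = make_classified_pairs(
    FixtureSpec(n_pairs=200, protein_len=100, rna_len=50,
                separation=6.0, seed=42))
results = RpiModel.from_dataframe(table).fit()
results.cross_validate(k=10, seed=0)
print(results.summary())
```

prints

```
        RNA-Protein Interaction SVM Results
====================================================
No. observations:        200    Positives:      100
Features:                132    Negatives:      100
Kernel:           polynomial    Support vecs:    25
C: 1000       gamma: 1      coef0: 1      degree: 4
----------------------------------------------------
Training     ACC  100.0  PRE    1.000  REC    1.000  FSC    1.000  AUC    1.000
10-fold CV   ACC  100.0  PRE    1.000  REC    1.000  FSC    1.000  AUC    1.000
====================================================
```

The generator draws positive and negative pairs from Dirichlet feature
distributions whose divergence is set by `separation`; at `separation=6.0`
the classes occupy complementary feature cells, and the cross-validated SVM
recovers them perfectly (ACC 100, AUC 1.0). At `separation=0.0` the same
pipeline sits at chance (ACC ≈ 50, AUC ≈ 0.5), confirming the classifier
reports signal only when the data contain it.

The same workflow is available from the shell:

```sh
rpipred simulate --n-pairs 200 --separation 6.0 --seed 42 --out sim/
rpipred featurize --protein-fasta sim/proteins.fasta --pb sim/pb.txt \
    --rna-fasta sim/rnas.fasta --rss sim/rss.txt \
    --pairs sim/pairs.tsv --out sim/features.tsv
rpipred evaluate --features sim/features.tsv --k 10 --seed 0 --out report.json
rpipred train --features sim/features.tsv --out model.bin
rpipred predict --model model.bin --features sim/features.tsv --out preds.tsv
rpipred network --predictions preds.tsv --format sif --out net.sif
```

`rpipred extract` and `rpipred build-dataset` run the structure side:
parsing protein–RNA complexes from PDB files, labeling co-complex chain
pairs by the 3.40 Å contact rule, removing redundant pairs and applying the
length filters.

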