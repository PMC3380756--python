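# nonsenseq

Detection of **nonsense regions** in putative protein sequences.

Automated gene finding sometimes translates non-coding DNA, or translates a
real exon in the wrong reading frame.  The resulting stretches of residues
— nonsense regions — exist in no real protein, yet they sit inside protein
databases' putative records and bias composition-based analyses such as
intrinsic-disorder prediction.  `nonsenseq` is for computational biologists
who want to flag such regions: it synthesizes nonsense training sequences
from trusted gene models, trains a balanced neural-network ensemble on
windowed sequence features, and evaluates the predictor with
sequence-grouped cross-validation.

## Method in brief

For every gene with a trusted protein, the gene sequence is cropped to the
coding exons plus ≤ 120 nt of flanking non-coding sequence and translated
in all three reading frames with stop codons skipped.  Candidate stretches
matching the true protein verbatim for ≥ 10 residues are correct
translations and are removed; the remaining runs are nonsense by
construction, labeled by genomic origin (coding / non-coding central
codon nucleotide) and distance to the nearest exon border.

Each residue *i* is described by 23 features over a 41-residue window:
amino-acid frequencies *f₁…f₂₀*, entropy *H = −Σ fₐ log₂ fₐ*, flexibility
*Σ fₐ sₐ*, and |net charge| / mean hydropathy.  An ensemble of ten
23→20→1 logistic networks is trained on samples balanced over class,
predicted disorder, origin and border proximity (targets 0.1/0.9); the
mean member output is the nonsense score, thresholded at 0.5.  Evaluation
uses 10-fold cross-validation grouped so that a gene's protein and its
nonsense segments always share a fold, reporting sensitivity (nonsense
class), specificity (true class), balanced accuracy = (sens + spec)/2,
and ROC AUC, overall and per stratum.

Everything runs offline: a genome simulator generates annotated GFF3+FASTA
genomes with the coding/non-coding compositional contrast the method
exploits.

## Worked example

```
nonsenseq simulate --genes 15 --seed 9 --out demo/genome
nonsenseq synthesize --gff3 demo/genome/genome.gff3 \
    --fasta demo/genome/genome.fasta --out demo/synth
nonsenseq crossval --gff3 demo/genome/genome.gff3 \
    --fasta demo/genome/genome.fasta \
    --folds 5 --members 2 --seed 1 --out demo/cv
```

The `synthesize` step prints

```
15 true proteins, 92 nonsense segments, 0 genes excluded
```

— one representative protein per gene and the nonsense segments recovered
from the three frame translations (frame-conflicted genes would be listed
in `excluded.tsv`).  The `crossval` step prints

```
per-residue balanced accuracy 0.9454, AUC 0.9879; per-protein balanced accuracy 0.9886
```

meaning that, scored out-of-fold, ~95% of residues are correctly assigned
to the true-protein vs. nonsense class on average across the two classes,
and aggregating residue scores to whole sequences separates true proteins
from nonsense segments almost perfectly.  `demo/cv/` then holds the
stratified metric table, per-sequence nonsense contents and out-of-fold
scores; `nonsenseq report` turns these into threshold sweeps, content
histograms and total-content margins, and `nonsenseq train` / `predict` /
`impact` fit and apply a standalone ensemble and estimate per-feature
influence by finite differences.

The same pipeline is available as a library:

```python
from nonsenseq import GenomeSimParams, simulate_genome, run_benchmark_cv
sim = simulate_genome(GenomeSimParams(n_genes=50, seed=7))
result = run_benchmark_cv(sim.genes)
print(result.report.overall.balanced_accuracy)
```

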