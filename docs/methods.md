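# Methods

## Problem and model

Automated gene annotation makes mistakes: predicted exons can extend into
non-coding DNA, and true exons can be translated in the wrong reading
frame.  Either error injects stretches of residues into a putative protein
record that exist in no real protein — *nonsense regions*.  Because those
stretches have unusual amino-acid composition, they confuse downstream
composition-based sequence analysis, most notably predictors of intrinsic
disorder, and can bias genome-wide disorder-content estimates.

`nonsenseq` treats nonsense detection as per-residue binary classification.
Since no curated catalogue of nonsense regions exists, training data are
*synthesized* from genes with trusted protein products:

1. **Crop.** Remove all non-coding nucleotides more than 120 nt from the
   closest coding exon.  The retained flanks are the non-coding sequence a
   gene finder could plausibly absorb into a predicted exon.
2. **Translate.** Read the cropped sequence in all three frames, skipping
   stop codons (and codons containing N) rather than truncating.
3. **Mask.** Any candidate stretch that matches the gene's true protein
   verbatim for ≥ 10 consecutive residues is a correctly translated exon
   and is removed.  Matching is exact common-substring matching, not scored
   alignment: a correct-frame exon translation matches *verbatim*, which is
   precisely the phenomenon the step must remove, and scored alignment
   would introduce parameters the procedure does not need.
4. **Keep the rest.** Maximal unmatched runs of ≥ 30 residues become the
   nonsense training set, each residue labeled by the genomic origin of its
   codon's central nucleotide (coding / non-coding) and by the distance of
   that nucleotide to the nearest exon/non-coding border.

The classifier is an ensemble of 10 small neural networks (23 inputs → 20
logistic hidden units → 1 logistic output) whose mean output is the
per-residue nonsense score.  Features per residue, over a 41-residue window
truncated at sequence ends (no padding, frequencies normalized by the
actual window size): the 20 amino-acid frequencies, their Shannon entropy
(local complexity), mean chain flexibility, and |net charge| / mean
hydropathy.  Targets are encoded 0.1 / 0.9 (true / nonsense) and residues,
or whole sequences via their mean score, are classified at 0.5.

## Balancing

Residue classes are heavily imbalanced (three frames of gene plus flanks
versus one protein), and systematically skewed in predicted disorder and
in origin.  Each network therefore trains on a balanced sample that
equalizes, by downsampling without replacement:

* true vs. nonsense residues;
* predicted-ordered vs. predicted-disordered residues within each class;
* coding-origin vs. non-coding-origin residues within the nonsense class;
* near-border (≤ 50 nt) vs. far-border residues within each class.

Equalization runs on the cross-product of the applicable bins: the 8
nonsense cells (disorder × origin × border) are downsampled to their common
minimum *c*, the 4 true cells (disorder × border) to 2*c*, which satisfies
every marginal equality simultaneously.  The sample is then capped at 8%
(train) and 2% (validation) of the available residues; windows of
neighbouring residues overlap heavily, so subsampling costs little
accuracy.  Each ensemble member draws its own sample with seed
`base_seed + member_index`; an empty required cell is an error, not a
silent degradation.

## Training

The fitting procedure is a design choice of this package: features are
standardized (location/scale from the full available pool, shared across
members), weights are initialized from a seeded normal scaled by fan-in,
and full-batch Adam (learning rate 0.05) minimizes squared error for at
most 300 epochs with early stopping on validation squared error (patience
15, keeping the best-epoch weights).  Training is bitwise reproducible
under a fixed seed.  All of this is recorded in the ensemble metadata and
the saved model JSON.

## Evaluation

Cross-validation is 10-fold and grouped: all residues of a sequence share
a fold, and — one step stricter — all sequences derived from one *gene*
(the representative protein and its nonsense segments) share a fold, so no
fold can train on windows overlapping its own test material.  Each fold's
10-network ensemble scores only its held-out fold; the retained bank of
fold models, averaged, is the predictor for genuinely unseen sequences.

With nonsense as the positive class: sensitivity = accuracy on nonsense
residues, specificity = accuracy on true-protein residues, balanced
accuracy = their mean (the appropriate summary under imbalance), plus ROC
AUC with ties counted half.  Stratified reports repeat this for
ordered/disordered residues (both classes restricted) and for nonsense
origin (positives restricted, negatives always the full true set, so both
origin rows share one specificity).  Per-sequence summaries are *nonsense
content* (fraction of residues scoring > 0.5) and the mean score; at the
0.5 threshold the margin in total nonsense content between the nonsense
and true sets equals sensitivity + specificity − 1 by construction, which
the test suite asserts exactly.  Disorder–nonsense coupling is summarized
by the Pearson correlation between per-sequence disorder content and
nonsense content with R² and the slope's t-test p-value.

Feature influence is the mean forward-difference partial derivative of the
ensemble output with respect to each input, taken at every point of a
balanced sample on the standardized feature scale with ε = 0.01 (ε is a
numerical choice; a two-ε report at 0.01 vs 0.005 guards against a bad
step size).  For an affine predictor the estimator recovers the
coefficients exactly.

## Disorder scores

Per-residue disorder predictions enter only as labels for balancing and as
the DC axis of the correlation analysis.  The package does not implement a
published disorder predictor; it exposes a provider interface that reads
externally computed per-residue scores from TSV, plus a built-in
deterministic surrogate: the 41-window frequency difference between
disorder-promoting {R,Q,S,E,K,G,P} and order-promoting {W,Y,F,I,L,V,C,N}
residues squashed through a logistic (score 0.5 at equal content, binary
at 0.5).  All disorder-dependent outputs are therefore labeled by the
provider used; numeric parity with any specific published predictor is not
claimed.  The flexibility scale is the normalized B-factor-derived scale
of Vihinen and colleagues; hydropathy is Kyte–Doolittle rescaled to [0,1]
by (h + 4.5)/9; both are replaceable via TSV.  Net charge counts K,R as
+1, D,E as −1 and treats H as neutral.

## Synthetic benchmark

Real curated genomes cannot be bundled, so the generator produces
annotated genomes that reproduce the *contrasts* the method exploits,
nothing more:

* exon/intron/UTR architecture (1–8 coding exons of 60–300 nt, total a
  codon multiple; introns 60–2000 nt; UTRs 0–300 nt; genes emitted on both
  strands; ~30% of eligible genes get a second isoform skipping one
  frame-preserving internal exon);
* proteins as alternating ordered/disordered blocks (disordered fraction
  0.3, geometric block length with mean 60 aa) drawn from two composition
  regimes — order-promoting residues up-weighted 2.5× in ordered blocks,
  disorder-promoting in disordered blocks;
* coding DNA by reverse translation with uniform synonymous codon usage
  (stop-free in frame 0 by construction; no stop codon is appended since
  translation skips stops anyway);
* non-coding DNA from an order-0 model with GC 0.55.

Under these defaults the pooled composition of frame-shifted and
non-coding translations differs from the true proteins by total-variation
distance ≈ 0.25, a cleaner contrast than real genomes exhibit.
Benchmark results (the 200-gene, generator-seed-42 profile) therefore
validate the *machinery* — synthesis, balancing, training, grouped
evaluation — and bound what the pipeline can achieve on ideal input; they
do not estimate accuracy on real annotated genomes, which have codon bias,
repeats, composition heterogeneity and annotation noise the generator
deliberately omits.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open in transcription orientation
  everywhere; GFF3 conversion happens only at the I/O boundary.
* IUPAC ambiguity codes other than N are mapped to N on read; codons
  containing N are skipped with a logged count.
* Internal stops in an annotated CDS are skipped with a warning (the same
  rule the synthesis translation uses), not treated as fatal.
* Genes whose isoforms translate a shared exon in different codon
  alignments are excluded from both classes, as are genes whose exon-union
  concatenation admits no single frame.
* Border distance is measured from the nearest exon/non-coding junction,
  the adjacent nucleotide having distance 1; for a gene with no such
  junction (single exon, no UTR) the distance to the nearer sequence end
  is used instead.
* A residue that could map to several true-protein matches is masked if
  *any* qualifying match covers it (order-independent union).
* The window at a sequence end is truncated, never padded.
* The charge/hydropathy denominator carries a δ = 1e-6 guard.

## Limitations

* The nonsense/true contrast in the benchmark is generated, hence
  optimistic; reported benchmark accuracies are upper bounds of machinery
  quality, not field performance estimates.
* The disorder surrogate is a monotone function of the same composition
  window the classifier sees, which couples the disorder bins to the
  features more tightly than an independent predictor would.
* One gene is one locus: overlapping genes and trans-splicing are out of
  scope, as is any organism-specific modeling.
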