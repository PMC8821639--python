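# Methods

## Problem and model

The package classifies protein primary sequences as pore formers or not.
Sequences are zero-padded to a fixed length L, encoded per residue, and
passed to a small 1D convolutional network:

conv(25 filters, kernel 100, over all channels) → ReLU → max-pool(5) →
conv(25 filters, kernel 50) → ReLU → max-pool(5) → dropout(0.25) →
flatten → one dense unit → sigmoid.

The sigmoid output is read as the probability of pore-forming character.
Training minimizes mean squared error between the sigmoid output and the
0/1 label. The MSE-on-sigmoid choice (rather than cross-entropy) keeps the
output on [0, 1] and trains stably at this scale; its gradient through the
sigmoid, 2(p − y)p(1 − p)/n, vanishes at saturation, which is visible as a
slow first epoch or two but is harmless at the problem sizes used here.

Choices the architecture description leaves open were fixed as follows:
max pooling (the standard reading of "pooling"); 25 filters in the second
convolution (mirroring the first); a single output unit directly after
flatten; sigmoid output (forced by the [0, 1] probability contract with MSE
loss); Adam at learning rate 1e-3, 30 epochs, batch 32 (configurable). The
network is implemented directly on NumPy — convolutions as
im2col + matmul, hand-derived backward passes, float32 throughout. All
randomness (Glorot init, shuffling, dropout masks) comes from one seed, so
training histories and fitted weights are bit-reproducible per platform.

## Encodings

* one-hot: 28 channels — 20 canonical residues, extended codes B J O U X Z,
  the stop artifact `*`, and a dedicated pad channel. The pad position is a
  real indicator (pad channel = 1), which is what makes the space
  28-dimensional; every row sums to exactly 1.
* Atchley: 5 channels of physicochemical factor scores per residue
  (polarity/accessibility, secondary-structure propensity, size, codon
  composition, charge), shipped as a TSV data file that is the single
  source of truth; pad rows are all-zero ("zero padding" in the literal
  sense). Ambiguity codes: B = mean(D,N), Z = mean(E,Q), J = mean(I,L),
  X = mean of all 20, U → C, O → K, `*` → zeros.
* combined: columnwise concatenation, 33 channels; slicing channels 0–27
  reproduces one-hot bit-exactly.

The default pad length is 2000 (the curation maximum) so a single encoder
configuration covers any curated dataset; the synthetic benchmark uses 400.

## Curation

* Length window 50–2000 residues, boundaries inclusive (the filter
  *eliminates* strictly shorter/longer sequences).
* Positive de-redundancy: greedy longest-first clustering at 70% identity
  (CD-HIT convention; ties broken by id), keeping one representative per
  cluster. Identity is defined on the optimal global (Needleman–Wunsch)
  alignment with BLOSUM62, gap open 10 / extend 1, as identical columns
  divided by alignment length including gap columns. Global rather than
  local identity was chosen for reproducibility without external binaries;
  the alignment engine is Biopython's PairwiseAligner. Co-optimal
  alignments can differ in identity fraction; the implementation takes the
  aligner's first optimal alignment, and the test oracle therefore checks
  exact score equality (a tie-free quantity) plus identity equality on
  substitution-only pairs where the gapless alignment is uniquely optimal.
* Negative purge: each negative's best Smith–Waterman hit against the
  positive set is converted to an E-value with the Karlin–Altschul formula
  E = K·m·n·exp(−λS), λ = 0.267, K = 0.041 (the gapped-BLOSUM62 regime);
  negatives with E ≤ 0.01 are removed. This keeps the pipeline
  self-contained and offline; the constants are an approximation to what a
  full BLASTP run would compute, adequate for a 0.01 cutoff because planted
  homology and chance similarity differ by orders of magnitude in E.
* J/O/U are outside BLOSUM62's alphabet and are mapped to L/K/C for
  alignment purposes only; sequences are never rewritten.

## Evaluation protocol

Randomized 80:20 train/test splits, stratified by label (plain
randomization can produce degenerate test sets at desk scale), repeated
over trials with per-trial seeds; per-epoch loss and accuracy recorded on
both sides. ROC curves sweep all distinct score thresholds (tie-grouped,
via scikit-learn) with trapezoidal AUC — equal by construction to the
tie-corrected Mann–Whitney statistic, which the tests verify by exhaustive
pair counting. Per-class curves: each positive family vs negatives;
a "negative" curve treating negatives as the detection target on inverted
scores (the only reading under which a negative-class ROC exists for a
binary scorer); and a macro average, the mean TPR on a fixed 101-point FPR
grid. The grid average pins TPR(0) = 0, so a perfect classifier's average
curve has area 0.995, not 1 — a resolution artifact, documented rather
than hidden.

Held-out-family evaluation scores a family absent from training and counts
calls at threshold 0.5 (the counting threshold is not fixed by the
probability contract; 0.5 is the symmetric default and configurable). The
harness refuses to run if any holdout id appears in training.

## Synthetic benchmark

The generator stands in for the real training corpus (public-database
positives, a culled-PDB negative set) with a controllable, honest test
signal; it makes no attempt to mimic real pore-former biophysics
(amphipathic periodicity, β-hairpin registers). Positives are i.i.d.
background chains plus two signal components scaled by `signal_strength`
s ∈ [0, 1]:

* motifs: each family owns 3 motifs of 8–15 residues drawn once from a
  seeded stream; round(s · 3) non-overlapping copies are planted per
  sequence (all three at s = 1, none at s = 0);
* composition: the residue distribution is mixed toward hydrophobic
  residues with weight 0.3·s.

Two components exist so that one-hot (motif-sensitive) and Atchley
(property-sensitive) encodings can be stressed separately. At s = 0 the
positives are distributionally identical to background by construction.
The "novel" holdout family shares the composition bias but draws motifs
verified disjoint from every training motif — the same-physics /
different-sequence scenario that defeats homology search. Defaults: 100
sequences per training family (2 families), 200 negatives, 50 holdout,
lengths uniform on [100, 400] — large enough for the signal-recovery and
generalization experiments, small enough that a full train/evaluate cycle
runs in minutes on one CPU; the full 50–2000 window remains available
through the config. Each generator component draws from its own
(seed, name)-derived stream, so adding a family never perturbs the
negatives, and a JSON manifest with SHA-256 checksums makes regeneration
verifiable.

Passing tests on this benchmark show that the pipeline recovers a planted
signal exactly when one exists and generalizes across motif content within
a shared property bias; they say nothing about accuracy on real proteins,
which depends on data the generator does not emulate.

## Dataset assembly at benchmark scale

`make_benchmark` returns the curated-dataset container directly: generated
records already satisfy the length window and id-disjointness, so the
O(n²) alignment steps are not re-run on data that cannot violate them.
`assemble_dataset` composes the three curation steps for real FASTA input
and is exercised on toy sets in the tests.

## Known limitations

* The Karlin–Altschul constants are fixed, not fitted per scoring system;
  E-values are approximate (fine for a coarse purge cutoff, not for
  reporting significance). Because chance Smith–Waterman scores grow with
  sequence length and with shared composition bias, the purge errs on the
  conservative side for long sequences: it may remove negatives a full
  BLASTP run would keep. Raise `purge_evalue` if retention matters more
  than purity.
* Greedy clustering depends on processing order by design; it reproduces
  the CD-HIT convention, not an optimal clustering.
* Training at the full 2000-residue pad length with the default kernels is
  supported but slow on one CPU; the shipped experiments use length 400.
* MSE loss gives weaker gradients than cross-entropy when the sigmoid
  saturates; with the default learning rate this costs a few epochs at
  most.
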