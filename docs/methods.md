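# Methods

## Model

`chromloop` treats loop calling as binary classification of bin pairs. The
input for a pair (i, j) is a two-channel 23x23 image: the local contact
submatrix (below-diagonal cells mirrored from the upper triangle, absent
entries zero) and the outer product of the accessibility values over the
window's row and column bins. The "Cartesian product" construction of the
accessibility matrix is realized as the outer product A[r][c] = x[r]·y[c]:
it is the standard two-dimensional lift of two 1D signals and produces a
matrix on which the window normalization is well defined.

Both channels are normalized per window and per channel:
`M ← log10(1 + M)` followed by `M ← M / (1 + max M)`, where the maximum is
taken over the logged window. The two steps are applied sequentially and
the all-zero window is a fixed point. A per-window (rather than
per-chromosome) maximum keeps each window self-normalized as an image; this
matters because absolute contact counts vary by orders of magnitude across
genomic distance.

### Architecture

Three convolutional blocks [conv → batch norm → ReLU → dropout 0.2], one
terminal global average pooling, then FC(64) → BN → ReLU → FC(64) → BN →
ReLU → FC(1) → sigmoid. Batch normalization follows each convolution
(before the ReLU) and each dense layer. Default filter counts are
(32, 64, 128); kernels are (9, 9, 7) applied *without* padding, so the
spatial extent shrinks 23 → 15 → 7 → 1 and the pooled feature vector
describes the window *as seen from its center*.

The kernel/padding choice is deliberate and load-bearing. A stack of
same-padded convolutions followed by global average pooling is exactly
translation-invariant: a loop signature anywhere in the 23x23 window
produces the same pooled features, so every pixel within ~11 bins of a true
loop scores alike and pooled candidate clusters cannot resolve the loop
pixel (we measured mean probability 0.87 at Chebyshev offset 0 versus 0.82
at offset 8 for a same-padded 3x3 stack). With the unpadded (9, 9, 7) stack
the probability falls from 0.90 at the center to 0.14 six bins away, and
cluster representatives land on the planted pixel. Kernels, filter counts
and padding remain configurable (`ModelConfig`).

### Training

Mean binary cross-entropy (natural log; predictions clamped 1e-7 from the
boundaries), optimized with Adam (lr 0.001, default betas, batch 128),
shuffling each epoch with a seeded generator. Chromosome-level splits
follow leave-one-chromosome-out: the test chromosome is held out entirely
and the remaining chromosomes are partitioned 80/20 into train and
validation sets, with a floor of one validation chromosome whenever at
least two non-test chromosomes exist (otherwise the three-chromosome
synthetic study would have no validation signal at all).

Two numerical choices stabilize training when the dataset is small:

- **Batch-norm recalibration ("precise BN").** Dropout sits upstream of the
  next block's batch norm, so running statistics collected in training mode
  are inflated relative to inference-time activations. With few windows per
  epoch this produced a large train/eval gap. Before every validation pass
  (and in the finally returned model) the BN statistics are recomputed in
  one clean pass with dropout disabled.
- **Weight averaging.** The validated and returned parameters are an
  exponential moving average (decay 0.98) of the per-epoch weights. When an
  epoch is a single optimizer step, individual iterates are noisy; the
  average has a smoother decision boundary. Setting `ema_decay=0` restores
  raw-weight evaluation.

Checkpoint selection keeps the epoch with the best validation PRAUC, ties
broken by lower validation loss; training stops at `max_epochs` or after
`patience` epochs without improvement. On separable data PRAUC saturates at
1.0 early, so the loss tie-break is what lets training proceed to a
well-converged, well-calibrated model.

## Calling

Stage 1 scores every stored (non-zero) pixel with
`min_dist ≤ j − i ≤ max_dist` (defaults 3–300 bins, i.e. 30 kb–3 Mb at
10 kb) whose window lies inside the chromosome, using exactly the training
window construction. Stage 2 keeps candidates whose contact value strictly
exceeds the per-chromosome candidate mean, then applies the probability
threshold, then pools survivors by single-linkage clustering under
Chebyshev distance ≤ radius (default 2 bins), reporting each cluster's
highest-probability pixel (ties: higher contact value, then smaller (i, j)).

The operating threshold deserves care. The probability scale of a small
CNN shifts with training stochasticity and map depth, so a fixed 0.5 cutoff
admits a variable amount of marginal background. `calibrate_threshold`
chooses the threshold on a calibration chromosome (here: the validation
chromosome) so that the pooled call count matches an expected per-
chromosome loop count — the same count-matched operating-point logic used
when comparing replicates of different depth. The end-to-end tests and the
acceptance script use this calibrated operating point; `CallParams.threshold`
(default 0.5) applies when calling without calibration.

Binomial downsampling replaces each raw count by a Binomial(count,
fraction) draw, dropping zeros; it is defined on raw integer counts only.

## Evaluation

- Precision/recall/F1 at a threshold (prediction positive iff p ≥ t), PRAUC
  by all-thresholds step integration (no interpolation), as implemented by
  scikit-learn's average precision.
- APA: elementwise mean of the (2f+1)² raw-value windows over loops with
  distance ≥ 2f+1 and in-bounds windows (defaults f = 10, corner 6). The
  score divides the center by the mean of the 6x6 block in the corner
  nearest the matrix diagonal — the short-distance corner, which is the
  conservative background choice since contact frequency rises toward the
  diagonal.
- Matching: exact (both anchor bins equal) or tolerant (each anchor's ±tol
  region overlaps the partner's, i.e. center distance ≤ 2·tol per anchor;
  tol = 10 kb default). Counts are of matched elements per side.
- Distance profiles: proportions over half-open genomic-distance bands.

## Synthetic studies

The generator emulates the structure of a deep, loop-rich Hi-C study at
desk scale. Per chromosome (default 3 chromosomes x 2000 bins at 10 kb):

- Background: contact at distance d is Poisson with mean
  `c·(d+1)^−α`, c = 1200, α = 1.3, simulated to 320 bins. The amplitude
  corresponds to a deeply sequenced (billions of cis-reads) combined map —
  the regime in which pixel-level loop classification is well posed; the
  exponent is in the range observed for mammalian intra-chromosomal decay.
- Loops: 30 per chromosome, centers pairwise ≥ 12 bins apart (Chebyshev),
  anchor distances log-uniform between 3 and 150 bins (30 kb–1.5 Mb) —
  loop-distance distributions are short-range heavy in enrichment data.
  Each loop multiplies the local mean by `1 + (s−1)·G` with a unit-peak
  Gaussian kernel (σ = 1.5 bins) and s = 10, a strong point enrichment of
  the kind anchor-targeted assays validate.
- Accessibility: baseline 1.0 plus Gaussian peaks (height 5, σ = 0.8 bins —
  ATAC peaks are sub-bin at 10 kb) at every loop-anchor bin and at 40 decoy
  positions per chromosome, plus zero-truncated Gaussian noise (σ = 0.5).
  The decoys matter: real open-chromatin tracks have far more peaks than
  loop anchors, and without them a classifier can succeed from the
  accessibility channel alone, leaving the anchor-crossing false-positive
  mode untested.

`simulate_study` writes triplet text, a cool-dialect HDF5 container, a
bedGraph, a truth BEDPE and a JSON manifest; identical parameters produce
byte-identical bundles.

What the generator does **not** emulate: TADs and compartments (block
structure around the diagonal), balancing biases and per-bin coverage
variation, inter-chromosomal contacts, replicate-level biological
variability, and realistic ATAC fragment-level noise. Passing the
end-to-end tests therefore demonstrates that the pipeline's machinery —
window construction, learning, filtering, pooling, matching — recovers
planted structure under realistic depth and decay, not that the classifier
transfers to any particular cell type's data.

## Problem sizes used in tests and the acceptance script

The default synthetic study (3 x 2000 bins, 30 loops/chromosome) yields 60
labeled windows per chromosome; under leave-one-chromosome-out that is one
training and one validation chromosome. Desk-scale runs therefore use
filter counts (8, 16, 32) and a 300-epoch budget with patience 60 — at 60
windows an "epoch" is a single optimizer step, so this matches the step
budget that batch-128 training implies at realistic dataset sizes. The
window-classification surrogate tests run at a few hundred windows per
class. These sizes are the package's choices for its own test fixtures;
the library defaults (filters (32, 64, 128), max 30 epochs, patience 5)
are appropriate for datasets with thousands of training windows.

## Degenerate inputs and tie-breaks

- All-zero windows normalize to all-zero and receive a valid probability.
- Anchor midpoints exactly on a bin boundary bin to the left.
- Duplicate mirrored triplet entries are summed; pixels touching a
  NaN-weight bin are dropped when balancing.
- `filter_by_frequency` uses a strict inequality, so a chromosome whose
  candidates all share one value yields no calls.
- Pooling tie-breaks: probability, then contact value, then lexicographic
  (i, j) — deterministic for any input order.
- `sample_negatives` falls back to the nearest available distance when a
  drawn distance has no remaining eligible pixels (logged), and raises only
  when the eligible pool is exhausted.

## Known limitations

- The NumPy network trains on CPU; it is sized for 23x23 windows and small
  filter banks, not for transfer to larger images.
- Scoring cost is linear in stored pixels; a deeply sequenced 2000-bin
  chromosome (~400k candidates) scores in about a minute per chromosome
  with the desk-scale configuration.
- Threshold calibration assumes the calibration chromosome's loop density
  is representative of the target chromosome.
- The cool dialect covers single-resolution bins/pixels/weights containers;
  multi-resolution (mcool) pyramids and `.hic` files are out of scope.
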