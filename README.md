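# chromloop

Genome-wide chromatin-loop calling from Hi-C contact maps fused with a 1D
accessible-chromatin track, using a small two-channel convolutional
classifier.

## The problem

Chromatin loops appear in a Hi-C contact matrix as focal enrichments: a bin
pair (i, j) whose contact frequency exceeds the local distance-decay
background. Loop anchors are typically accessible chromatin (CTCF/cohesin
sites, active enhancers and promoters), so a 1D accessibility signal
(ATAC/DNase) carries complementary evidence. `chromloop` classifies
candidate bin pairs by looking at the 23x23 window of the contact matrix
around each pair together with a matched 23x23 accessibility matrix, and
pools high-scoring pixels into loop calls. It is aimed at computational
genomicists who have a binned intra-chromosomal contact matrix (cool-dialect
HDF5 or sparse triplet text), an accessibility track (bedGraph or bigWig),
and a set of enrichment-validated interactions (ChIA-PET / HiChIP /
Capture Hi-C BEDPE) to train on.

## The method

For a bin pair (i, j) at resolution r (10 kb default):

- **Channel 1** is the w x w (w = 23) submatrix of the contact map centered
  on (i, j), with below-diagonal cells mirrored from the upper triangle.
- **Channel 2** is the outer product `x yᵀ` of the per-bin accessibility
  values over the window's row and column bins.
- Each channel is normalized per window: `M ← log10(1 + M)`, then
  `M ← M / (1 + max M)`, mapping any window into [0, 1).

Windows centered on validated interactions are positives; an equal number of
negatives is drawn from non-zero pixels, most matching the positives'
empirical distance distribution and a minority (`far_fraction = 0.2`) lying
beyond the maximum positive distance. The classifier is three blocks of
[convolution → batch norm → ReLU → dropout 0.2], global average pooling, two
64-unit dense layers and a sigmoid output, trained with binary cross-entropy
under Adam (lr 0.001, batch 128) using a leave-one-chromosome-out protocol
(one test chromosome; the rest split 80/20 into train/validation
chromosomes). Default kernels (9, 9, 7) without padding shrink the window
23 → 15 → 7 → 1 so the classifier is center-referenced (see
`docs/methods.md`).

Calling proceeds in two stages: every stored pixel within the distance range
(30 kb – 3 Mb) is scored; candidates are kept if their contact frequency
exceeds the per-chromosome candidate mean and their probability passes the
operating threshold; survivors are pooled by single-linkage clustering under
Chebyshev distance ≤ 2 bins, keeping each cluster's highest-probability
pixel. The operating threshold can be calibrated on a held-out chromosome to
yield an expected number of calls (`calibrate_threshold`). Binomial
downsampling of raw counts supports sequencing-depth robustness studies, and
the evaluation module provides precision/recall/F1/PRAUC, aggregate peak
analysis (APA), exact and ±10 kb tolerant loop matching, and
distance-band profiles.

A synthetic-data module generates complete studies — power-law
distance-decay Poisson contact maps with planted Gaussian loop enrichments,
accessibility tracks peaked at loop anchors (plus decoy peaks), BEDPE truth
sets — in exactly the formats the readers consume, so the entire pipeline is
testable without downloads.

## Worked example

```python
import chromloop as cl

# synthesize a study: 3 chromosomes x 2000 bins (10 kb), 30 loops each
params = cl.SimParams(seed=7)
bundle = cl.simulate_study(params, "study/")

maps, tracks, truth, datasets = {}, {}, {}, {}
for c in bundle.chroms:
    maps[c] = cl.read_contact_map(str(bundle.cool_path), c, 10000)
    tracks[c] = cl.read_accessibility(str(bundle.bedgraph_path), c, 10000,
                                      maps[c].n_bins)
    truth[c] = [t for t in cl.read_interactions(str(bundle.truth_path), 10000)
                if t.chrom == c]
    datasets[c], _ = cl.build_dataset(maps[c], tracks[c], truth[c], seed=11)

train_chroms, val_chroms, (test_chrom,) = cl.loco_split(bundle.chroms, "chr3",
                                                        seed=5)
model = cl.train(
    cl.init_model(cl.ModelConfig(seed=3, filters=(8, 16, 32))),
    [w for c in train_chroms for w in datasets[c]],
    [w for c in val_chroms for w in datasets[c]],
    cl.TrainConfig(seed=3, max_epochs=300, patience=60),
)

# calibrate the operating threshold on the validation chromosome, then call
val = val_chroms[0]
ff_val = cl.filter_by_frequency(cl.score_chromosome(model, maps[val], tracks[val]))
thr = cl.calibrate_threshold(ff_val, target_count=len(truth[val]))
ff = cl.filter_by_frequency(cl.score_chromosome(model, maps[test_chrom],
                                                tracks[test_chrom]))
calls = cl.pool_candidates(cl.filter_by_probability(ff, thr), radius=2)

na, nb, _ = cl.match_loops(calls, truth[test_chrom], mode="tolerant")
print(f"{len(calls)} calls; precision {na/len(calls):.3f} "
      f"recall {nb/len(truth[test_chrom]):.3f}")
print(f"APA score of truth loops: "
      f"{cl.apa(maps[test_chrom], truth[test_chrom]).apa_score:.2f}")
```

Output:

```
33 calls; precision 0.909 recall 1.000
APA score of truth loops: 3.36
```

33 loop calls on the held-out chromosome, of which 30 coincide with the 30
planted loops within ±2 bins (±20 kb) — precision 0.91 at full recall — and
the planted loops are ~3-fold enriched over their short-distance local
background in the aggregate peak analysis.

The same pipeline is available from the shell:

```bash
chromloop simulate --seed 7 --out study/
chromloop gen-samples --contacts study/contacts.cool \
    --track study/accessibility.bedgraph --positives study/truth.bedpe \
    --chrom chr1 --seed 11 --out chr1.h5
chromloop train --dataset chr1.h5 --dataset chr2.h5 --dataset chr3.h5 \
    --test-chrom chr3 --seed 3 --out model.npz
chromloop call --model model.npz --contacts study/contacts.cool \
    --track study/accessibility.bedgraph --chrom chr3 --out calls.bedpe
```

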