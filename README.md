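# gflseg

Joint segmentation and copy-number calling for SNP-array signals with a
**generalized fused lasso** (GFL).

Genotyping arrays measure, at every probe, a total-intensity signal (Log R
Ratio, LRR — ~0 at diploid copy number) and an allelic-ratio signal
(B Allele Frequency, BAF).  Copy-number variants (CNVs) shift the means of
these signals over runs of consecutive probes.  When several related
sequences are available — LRR and mirrored BAF of one subject, technical
replicates, tumor biopsies, members of a pedigree — change points tend to
be shared, and segmenting the sequences jointly is more powerful than one
at a time.  `gflseg` is for analysts who want that joint analysis as a
Python library plus a small CLI, with a synthetic-data generator to
exercise every stage against known truth.

## The estimator

For M sequences y on a shared grid of N probes (observed where the mask
d_ij = 1), the piecewise-constant means β minimize

    f(β) = ½ Σ_ij d_ij (y_ij − β_ij)²
         + Σ_i λ1,i Σ_j |β_ij|                       (baseline sparsity)
         + Σ_i λ2,i Σ_j |β_ij − β_i,j−1|             (fused lasso / TV)
         + Σ_j ‖λ3 ∗ (β_(j) − β_(j−1))‖₂             (group fused lasso)

The group term — an L2 norm across sequences of the jump at probe j —
makes a change point cheaper for every sequence once one sequence jumps
there.  The objective is minimized by an MM algorithm: each iteration
solves one symmetric positive-definite tridiagonal system per sequence,
O(MN) total, so whole chromosomes with hundreds of samples are practical.
Defaults for the penalties come from the noise level σ̂_i, the probe count
and the expected sharing proportion p; fitted jumps are then hard-
thresholded (a jump-scale "ruler" or a modified BIC) and each resulting
segment is assigned a copy-number state c ∈ {0,1,2,3,4} by a BAF+LRR
log-likelihood ratio with acceptance cut-offs r1 (evidence) and r2 (mean
shift).  See `docs/methods.md` for the full account.

## Worked example

Five samples, 1200 probes, every sample carrying a 30-probe deletion and a
40-probe duplication:

```python
import numpy as np
from gflseg import (CNVSpec, NoiseSpec, SegmentOptions, call_chromosome,
                    generate_cohort, score_detection, segment_chromosome)

specs = [
    CNVSpec(start=300, length=30, state=1, carriers=tuple(range(5))),
    CNVSpec(start=800, length=40, state=3, carriers=tuple(range(5))),
]
lrr, baf, truth = generate_cohort(5, 1200, specs, noise=NoiseSpec(lrr_sd=0.2), seed=42)

segments, jumps = segment_chromosome(lrr, baf, SegmentOptions(signals="both"))
calls = call_chromosome(segments, lrr, baf)
accepted = calls[calls.accepted]
print(accepted[["sample", "start_probe", "end_probe", "state", "lr"]].head(6).to_string(index=False))

table = score_detection(truth, accepted, labels=list(lrr.labels))
print(table[table.length_class == "all"][["type", "tpr", "fdr"]].round(2).to_string(index=False))
```

prints

```
 sample  start_probe  end_probe  state         lr
sample0          302        330      1 171.806442
sample0          803        840      3 169.572813
sample1          301        313      1  69.863643
sample1          314        325      1 101.864654
sample1          326        329      1  23.770180
sample1          801        840      3 201.484791
       type   tpr  fdr
        any 96.86  0.0
   deletion 96.67  0.0
duplication 97.00  0.0
```

Each accepted call is a segment with its state (1 = hemizygous deletion,
3 = one-copy gain) and the log-likelihood ratio supporting it; segment
boundaries land within a probe or two of the truth (301/330 and 801/840),
and the per-SNP true-positive rate / false-discovery rate confirm that
~97% of variant probes are recovered with no diploid probe miscalled.
Sample1's deletion is split into three adjacent fragments — cosmetic here,
since all three carry the correct state.

The same pipeline from the shell:

```sh
gfl simulate --scenario cohort --m 5 --n 1200 --seed 42 --out-prefix sim/run
gfl segment sim/run_sample*.tsv --signals both --out-segments segments.tsv
gfl call --segments segments.tsv sim/run_sample*.tsv --out calls.tsv
gfl score --truth sim/run_truth.tsv --calls calls.tsv --n 1200
```

Signal files are tab-delimited (`Name`, `Chr`, `Position`,
`<sample>.Log R Ratio`, `<sample>.B Allele Freq`); exported intervals are
BED-style 0-based half-open.

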