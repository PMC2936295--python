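# dinet

Inference of directed transcription-factor → gene regulatory networks
from short, replicated gene-expression time courses, with
sequence-level validation of the inferred edges.

Association measures such as mutual information (MI) detect that two
genes co-vary but not *which one drives the other*. When expression is
measured as a time series, the direction can be read off the temporal
structure. `dinet` does this with **directed information (DTI)**: for
two expression processes X and Y observed at N equidistant time points,

    I(X^N → Y^N) = Σ_{n=2..N}  I(X^n ; Y_n | Y^{n−1})
                 = Σ_{n=2..N} [ I(X^n ; Y^n) − I(X^n ; 0Y^{n−1}) ]

i.e. the dependence between X and Y after subtracting the part carried
by Y's own past (0Y^{n−1} is Y's lagged segment, realised as the
shifted sample pairs (x_t, y_{t−1})). Unlike MI, DTI is asymmetric:
I(X→Y) ≠ I(Y→X), and the larger direction points from regulator to
target.

The full pipeline mirrors how such networks are inferred in bacteria
(the motivating system is *E. coli* with 19 time-course experiments at
0/30/60/90 min):

1. **preprocessing** — select experiments on a common equidistant time
   grid; a missing final time point is filled by not-a-knot cubic
   spline interpolation from a later measurement.
2. **MI estimation** — B-spline fractional binning (primary) or
   Gaussian kernel densities (alternative), both in nats.
3. **DTI matrix** — I(TF → gene) for every TF × gene pair, pooling
   sample pairs across experiments (the grids are too short for
   per-experiment estimation).
4. **CLR significance** — each DTI is z-scored against its regulator's
   row and its target's column of the TF × gene matrix (null = "most
   pairs do not interact"); the cumulative z is the quadratic mean of
   the two clamped z-scores.
5. **Thresholding** — edges selected at a target *precision* (fraction
   of known edges among inferred ones, evaluated on the reduced graph
   of TFs/genes with known interactions), at a fixed count, or at a
   fixed z.
6. **Motif validation** — an edge is kept only if the target's 400-bp
   promoter contains a log-odds hit of the TF's position weight matrix
   (built from known binding sites) whose best occurrence overlaps a
   phylogenetically conserved interval by strictly more than 50%;
   accepted edges can be propagated across operons.

A synthetic-data module generates ground-truth networks, time courses,
promoters with planted binding sites, conserved intervals and partial
reference networks, so every stage is testable without downloads.

## Worked example

Run the complete pipeline on a synthetic benchmark (20 TFs, 200 genes,
150 true edges, 19 experiments × 4 time points):

```sh
$ dinet pipeline --out-dir demo --seed 7
INFO dinet: wrote synthetic benchmark to demo (150 true edges)
INFO dinet: wrote bspline DTI matrix (20 x 200) to demo/dti.tsv
INFO dinet: wrote z-score matrix to demo/zscores.tsv
INFO dinet: 155 edges selected (precision>=0.4 tau=1.76478); reduced-graph precision 0.400
INFO dinet: accepted 75 / 155 edges
INFO dinet: after operon expansion: 90 edges
```

At the 40% precision target the calibrated z threshold is 1.765,
selecting 155 edges. The motif + conservation filter keeps 75 of them
and operon expansion adds 15 more. `demo/report.json` compares both
networks against the generator's ground truth:

```json
{
  "inferred_precision_vs_truth": 0.3161290322580645,
  "n_inferred": 155,
  "n_validated": 90,
  "validated_precision_vs_truth": 0.3888888888888889
}
```

Sequence-level validation raises the fraction of true edges from 0.316
to 0.389 — the synthetic analogue of filtering inferred interactions
by conserved binding sites. Each stage is also available separately
(`dinet simulate|dti|mi|clr|threshold|validate`), reading and writing
plain TSV/FASTA/BED files, and the same operations are importable from
Python (`from dinet import dti_matrix, clr_zscores, ...`).

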