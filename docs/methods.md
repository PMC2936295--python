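# Methods

This note documents the models and estimators implemented in `dinet`,
the tunable parameters and their defaults, what the synthetic
benchmark does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Directed information on short replicated time courses

For two expression processes X and Y on a shared equidistant grid of
length N, directed information is

    I(X^N → Y^N) = Σ_{n=2..N} I(X^n ; Y_n | Y^{n−1}),

the information the history of X carries about Y's present beyond what
Y's own past already explains. Expanding the conditional term gives an
equivalent difference of two unconditional MIs per step,
I(X^n; Y^n) − I(X^n; 0Y^{n−1}), where the second term scores the
*shifted* pairing (x_t, y_{t−1}) — the Y-leads-X association.
Subtracting it from the same-time association leaves the causal X→Y
component. Two estimation regimes are provided:

* **pooled** (default): each MI term is estimated from scalar sample
  pairs pooled across experiments and time. With N = 4 and ~19
  experiments, per-experiment estimation is impossible; pooling trades
  stationarity assumptions for sample size. The now-term at step n
  pools (x_t, y_t) for t ≤ n; the lag-term pools (x_t, y_{t−1}) for
  2 ≤ t ≤ n. Two documented variants alter the sample sets:
  `include_zero_pad` keeps the literal (x_1, 0) padding pair of the
  0Y^{n−1} concatenation, and `match_samples` restricts the now-term
  to t ≥ 2 so both terms pool equally many pairs.
* **vector** (histogram estimator only): each experiment's segment is
  one vector-valued sample. In this regime the plug-in estimate
  satisfies the conditional-MI identity above *exactly*, which is how
  the test suite verifies the implementation against exhaustive
  enumeration at 1e−12.

Two consequences of the pooled default are worth knowing. First, the
now-term pools E·n pairs while the lag-term pools E·(n−1): their
small-sample biases differ, so raw pooled DTI values are shifted by a
direction-independent constant. This cancels in the directional
contrast DTI(X→Y) − DTI(Y→X) and is absorbed by the CLR background
correction, so no bias correction is applied. Second, DTI orients an
edge by comparing the same-time association with the reverse-shifted
one — this only works when the regulator's series is autocorrelated
(real expression sampled every 30 min strongly is). A hypothetical
memoryless regulator would leave no same-time footprint of its past
and its outgoing edges would be invisible to this statistic.

## Mutual-information estimators

All estimators report nats.

**B-spline fractional binning** (primary; default M = 10 bins, spline
order k = 3). Each variable is min-max scaled to [0, 1]; each
observation distributes a unit of mass over M bins according to the M
B-spline basis functions of order k on a clamped uniform knot vector
(a partition of unity, so weights sum to 1 per observation). MI is the
plug-in H(X) + H(Y) − H(X,Y) of the weighted histograms; with k = 1
this reduces to an ordinary equal-width histogram. The estimate is
provably ≥ 0 (the weighted joint is a genuine distribution with the
weighted marginals), invariant under affine transforms of either
variable, and symmetric.

*Known bias.* The estimator measures the MI of the binned, smoothed
variables, which is systematically below the continuous MI when the
dependence is strong relative to the bin resolution. Numerical
integration of the infinite-sample estimator on a correlated Gaussian
(ρ = 0.8) gives 0.310 nats against the continuous 0.511; at ρ ≤ 0.5
the deficit is within ~0.05. This is inherent to M = 10 / k = 3, not a
sampling artifact — rankings (which is what CLR consumes) are
unaffected, but absolute values at strong dependence are conservative.
Finite samples add a positive plug-in bias that partially masks the
smoothing deficit at small n; consistency toward the closed form is
therefore only observed in the noise-dominated regime (weak
dependence), and the test suite checks it at ρ = 0.3.

**Gaussian kernel densities** (alternative). Product kernels with
per-variable Silverman bandwidths h = σ̂ (4 / 3n)^{1/5}, joint and
marginal densities evaluated at the sample points (leave-self-in; the
simplicity is preferred over bias correction for the secondary
estimator). MI is the sample mean of log[f(x,y)/(f(x)f(y))] and may be
slightly negative under estimation noise; it is not clamped. On
correlated Gaussians at n = 2000 it tracks the closed form within a
few hundredths of a nat across ρ ∈ [0, 0.8].

**Plug-in histogram** (oracle). Exact plug-in MI for discrete symbol
vectors (scalar or vector-valued samples); used as the brute-force
reference in the DTI equivalence tests. Entropy terms are summed in
sorted order so symmetry is bitwise.

Zero-variance inputs define MI = 0 rather than raising: constant genes
occur in real matrices and carry no information.

## CLR significance

The null distribution of DTI for non-interacting pairs is estimated
from the data itself under the assumption that most pairs do not
interact: entry (i, j) is z-scored against row i (all targets of
regulator i) and against column j (all regulators of target j), each
component clamped at zero, and combined as the quadratic mean
sqrt((z_r² + z_c²)/2). All statistics are computed within the TF × gene
matrix only — never the full gene × gene matrix — using the sample
standard deviation (ddof = 1). Rows/columns with fewer than two valid
entries or zero spread contribute a component of 0. Clamping negatives
before combining is standard CLR practice; only positive z thresholds
are meaningful downstream. The literal quadratic *mean* differs from
the root-sum-of-squares variant by the constant √2, which any
precision-calibrated threshold absorbs. On i.i.d. Gaussian score
matrices (50 × 200) fewer than 2% of cumulative z-scores exceed 3, so
the correction does not manufacture significance; z is invariant under
location shifts and positive rescaling of the score matrix.

## Thresholding and precision

Precision = known / inferred, evaluated on the **reduced graph**: only
edges whose regulator has at least one known target and whose target
has at least one known regulator enter the computation, because
absence from an incomplete reference is not evidence against an edge.
`threshold_at_precision` scans the observed z values and returns the
*smallest* threshold whose edge set reaches the target precision —
i.e. the largest network at that precision — while the returned
network keeps all edges above the threshold, including those outside
the reduced graph. Ties in `edges_top_k` break deterministically by
(regulator, target).

## Sequence-level validation

Known binding sites (aligned, equal length) are summarised as a
position weight matrix with probability (count + c)/(n + 4c),
pseudocount c = 0.5 by default. Promoter windows are the 400 bp
upstream of the start site, supplied already oriented; coordinates are
window-local, 0-based, half-open. The scan scores
Σ log(p_pos(base)/q(base)) (uniform background q = 0.25 unless given)
at every offset on both strands, the minus strand reading the reverse
complement; non-ACGT positions contribute zero log-odds with a
warning. The default acceptance threshold for the best hit is the
minimum self-score of the PWM's own training sites, which guarantees
the known sites themselves pass. An edge is accepted iff a hit reaches
the threshold *and* the union of conserved intervals covers strictly
more than 50% of it (equality rejects). Accepted edges whose target is
the promoter-proximal gene of an operon propagate to the downstream
members, flagged as operon-derived.

This PWM log-odds scan stands in for constrained motif discovery: the
intent — find a promoter region resembling the known sites — is
honoured without reproducing a particular discovery algorithm's
internal model. The threshold choice has a documented consequence:
training sites score against a PWM they themselves built (their
mutations contribute counts), so the min-training-score threshold sits
above the typical score of an equally divergent *fresh* site. On the
planted-site benchmark (per-base substitution rate 0.1 for planted and
known sites alike) typical recovery is ~70–87% rather than >90%, while
false accepts on background promoters stay at ~0%. The filter is
deliberately conservative; lowering the threshold would trade
precision for recall.

## Synthetic benchmark

`simulate_topology` draws uniform random TF→gene edges (no self-edges)
with effects ± U(0.5, 1.5). `simulate_timecourses` advances

    x_{t+1,g} = tanh( φ·x_{t,g} + Σ_r W_{rg} x_{t,r} ) + ε,
    ε ~ N(0, noise_sd²),

with persistence φ = 1.0, noise_sd = 0.3, from N(0,1) initial states,
discarding a 3-step burn-in so the recorded 4-point window lies in the
stationary regime. The persistence term models transcript carry-over
between successive half-hour arrays and supplies the autocorrelation
that directed information requires (see above); without it, root
regulators are temporally white and no time-series method can orient
their edges. tanh saturation makes the dependence non-Gaussian on
purpose; a linear mode exists for analytic sanity checks (with φ = 1,
zero weights and zero noise it holds series exactly constant).
Defaults: 19 experiments × 4 time points at 30-min spacing, 20 TFs,
200 genes, 150 edges.

`simulate_promoters` writes 400-bp uniform-background promoters; true
targets receive a mutated consensus copy (rate 0.1) at a random
offset; the conserved interval covers the planted site entirely with
probability `conserve_fraction` and an unrelated window otherwise.
Genes without a planted site also get one random conserved window so
the conservation rule is exercised non-trivially on negatives.
`make_reference` keeps a uniform fraction of true edges, emulating
database incompleteness. `evaluate_recovery` reports precision, recall
and AUPR (trapezoidal over the ranked list, anchored at recall 0, ties
broken lexicographically).

What the generator does **not** emulate: microarray noise models,
operon-aware dynamics, TF-specific motifs (one consensus is shared by
all TFs, so the sequence filter tests *target* identity, not partner
identity), realistic promoter composition, or genome-scale coordinate
systems. Passing tests therefore demonstrate the pipeline's internal
correctness and its behaviour under a controlled generative model, not
performance on real compendia.

## Problem sizes and determinism

The packaged benchmark (20 TFs × 200 genes, 10 seeds) was chosen so
the full test suite and the acceptance script each complete in
minutes; larger networks scale linearly in TF × gene pairs. All
randomness flows through seeded `numpy` generators; the CLI pipeline
is byte-identical across reruns with the same seed, and output headers
carry a config hash for provenance.

## Known limitations

* Absolute B-spline MI values undershoot at strong dependence (above);
  use rankings or the kernel estimator when absolute nats matter.
* Pooled DTI assumes the pooled pairs are exchangeable across
  experiments and time; strong non-stationarity within the 4-point
  window violates this and is only partially mitigated by
  `match_samples`.
* The motif filter is conservative by construction (threshold
  guarantees training-site recall, not planted-site recall).
* One-step lag only; longer regulatory delays and conditioning on
  third genes are out of scope.
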