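# Methods

## The stimulus model

A block presents 400 tones drawn from two frequencies ("low", "high").
The analytic world treats the draws as i.i.d. Bernoulli with high-tone
probability p fixed within a block and drawn once per block from a prior
on [0, 1]. With a uniform prior, the joint law of the past-window count k
(high tones among the last N) and the next tone is exact:

    P(k, high) = (k+1)/((N+1)(N+2)),  P(k, low) = (N−k+1)/((N+1)(N+2)),

giving a uniform marginal over k and the Laplace rule of succession
P(high|k) = (k+1)/(N+2). The count is a minimal sufficient statistic:
ordering carries no extra predictive information. `OddballWorld` exposes a
Beta(a, b) prior hook (evaluated via log-Beta functions), but every
benchmark uses the uniform prior; other priors change numbers, not trends.
A full-sequence enumeration (`sequence_joint`) exists as a small-N oracle
and refuses N > 20.

Information quantities are in bits throughout, with 0·log 0 := 0. All
predictive probabilities lie in [1/(N+2), (N+1)/(N+2)], so every surprise
−log₂ p is finite.

## The IB solver

`ib_fixed_point` iterates the three self-consistent equations (encoder
update, marginal update, Bayes decoder update) at fixed β until the
largest per-row total-variation change of the encoder falls below 1e-10.
Exceeding the iteration cap returns a *flagged* result (`converged=False`
with the residual) rather than raising: capped points occur only in the
immediate vicinity of cluster-merge transitions, where the slow critical
mode moves the information coordinates negligibly.

The solver runs on the count alphabet (size N+1), not on the 2^N raw
pasts. This is exact — optimal IB solutions factor through a sufficient
statistic, and any encoder of the full past that depends only on the
count has identical complexity on either alphabet — and it is what makes
N = 50 feasible. The number of states defaults to N+1; more cannot help.

**Annealing direction.** The β-sweep (`sweep_beta`) anneals *downward*:
it starts at a large β from the exactly known maximum-complexity solution
(the identity encoder) and descends to β = 1 with warm starts. Ascending
annealing must *split* clusters at phase transitions, and in this problem
it reliably sticks in merged local optima (reaching, e.g., only 1.92 of
the 2.32 available bits at N = 4); descending annealing only ever needs
*merges*, which the fixed-point dynamics perform on their own. A fixed
deterministic perturbation (row-wise 1 + ε·sin((k+1)(m+1)), ε = 1e-3) is
applied between β steps to dislodge marginally stable iterates. The
solver uses no random numbers, so sweeps are reproducible bit for bit.

The top of the β grid is auto-calibrated per N (smallest power-of-4
multiple of 64·(N+2) whose solution reaches 99.9% of log₂(N+1)); the
bottom is β = 1, below which the IB solution is always trivial. After the
descent, complexity gaps wider than 0.1 bit are closed by geometric
bisection in β, and exactly `n_points` representations nearest to
uniformly spaced complexity targets are returned. The per-sweep iteration
cap is 4000 (the standalone `ib_fixed_point` default is 10⁵): a full
50 × 200 bank builds in under ten minutes on one core.

**Effective states.** Solver output can carry duplicate clusters — states
with equal decoders *and* proportional encoder columns, i.e. one cluster
split across two labels. `effective_states` merges duplicates (decoder
and input-posterior both within 1e-6 total variation) and counts states
with marginal mass above 1e-3. Equal decoders alone are deliberately not
sufficient for merging: in the full-past identity encoder, pasts with the
same count share a decoder yet are genuinely distinct states, and merging
them would change the representation's complexity — the 16 states of the
N = 4 full-past code must count as 16, not 5.

## Prediction errors

For a trial with past-count k and tone y, the representation yields one
error per state, −log₂ P(y|m), with weight P(m|k); the expected error is
their weighted mean. Averaged over the stationary joint this equals
H(future) − I(m; future), an identity the tests verify to 1e-9 for every
bank member with N ≤ 10. Traces drop the first 50 trials of each block
(burn-in) so every analysed trial has a full past for any N ≤ 50; the
burn-in is fixed, not N-dependent, and representation state never crosses
block boundaries (blocks are separate recordings).

## Fitting spike counts

Per (neuron, test frequency), trials of that tone are expanded into
(error per state, count) pairs weighted by P(m|k) and fitted by weighted
least squares; the weighted r² uses the weighted mean in both sums of
squares. Because all fitted trials share one tone, the expanded-set sums
collapse onto the histogram of past counts (trial count n_k and count sum
s_k per k), making each fit O(states²) regardless of trial number; a
dual-route test checks this contraction against an explicit WLS on the
expanded set. Degenerate fits (zero count variance, or zero predictor
variance as in the N = 1 equiprobable world) return r² = 0 with an
unidentified slope rather than failing.

One statistical property of this estimator deserves emphasis: when the
generating encoder is *soft* and the data arise from sampled latent
states, the expanded-set regression attenuates the slope (each trial's
count, produced by one sampled state, is paired with every state's error
— a within-trial errors-in-variables spread), while r² ranking across the
bank, good-set membership and argmax recovery are unaffected. Unbiased
recovery of (a, b) therefore holds for deterministic encoders such as the
sufficient statistic, and is tested there; slope magnitudes fitted under
soft representations should be read as lower bounds.

The grid search evaluates the full bank and records rmax², its argmax
(ties broken toward smallest N, then smallest complexity — the most
parsimonious representation), and the good set r² ≥ 0.9·rmax².
Significance: the observed rmax² must strictly exceed rmax² recomputed on
each of 20 within-block tone permutations (counts stay attached to trial
slots), a maximum-statistic test with nominal p < 1/21 ≈ 0.048.
Permutations are within-block to preserve each block's tone probability.
Population maps average, over cases passing rmax² ≥ 0.1, the indicator
that a cell (binned complexity × power, N × complexity, N × power)
contains a good representation of that case.

Response significance against spontaneous activity uses a one-sided
Mann–Whitney rank test at α = 0.05; the choice of test is this package's
(a rank test assumes least about count distributions).

## Variance partition and SSA

The noise variance conditions counts on (block, exact 7-gram of preceding
tones, current tone) over retained trials and averages within-group
variances weighted by group size. The unbiased scheme (n−1 divisors,
singletons excluded) can over-correct; the biased scheme (n divisors,
singletons contributing zero) is conservative and keeps the corrected
fraction — predictor variance over (total − noise) variance — inside
[0, 1] on well-sampled data. Out-of-range unbiased fractions are reported
as-is with a flag, never clipped.

The SSA index is computed per frequency: SI(f) = (d(f) − s(f)) /
(d(f) + s(f)) with d, s the mean counts when f is rare (10%) and common
(90%). This is the standard contrast from the SSA literature; it is
adopted here as the conventional formula rather than derived.

## Synthetic data

The generator emulates the recording protocol: blocks of 400 tones at
high-tone probabilities {10, 30, 50, 70, 90}% (main design: 10/50/90),
sequences drawn by default as fixed-count random permutations (exactly
round(p·400) high tones, matching the experimental construction) while
the analytic world is Bernoulli — that mild mismatch is inherent to the
paradigm and intentionally preserved; a `bernoulli` mode exists. Spike
counts follow count ~ noise(a·error + b) with Poisson or Gaussian noise;
the latent state is *sampled* from P(m|k) per trial, so the analysis
stage's latent-state weighting is genuinely exercised. Default ground
truth (a = 2 spikes/bit, b = 3 spikes, σ = 1, generating member N* = 10
at 2 bits) gives mid-range r² values comparable to well-modulated cortical
units. Gaussian counts are continuous (the generative model is affine in
the error); negative means are clipped at zero and the clip rate recorded.
Trials with an incomplete past (index < N) draw the state from the
marginal P(m); they are always removed by the burn-in before analysis.
Ground truth is serialized in a sidecar JSON, never inferred from names.

What passing tests on these data do *not* show: real spike counts are
integer, overdispersed, nonstationary (drift, adaptation beyond the
oddball effect), and possibly nonlinearly related to surprise; the
generator models none of that, so recovery results here bound what the
pipeline can do under its own assumptions, not cortical reality.

## Problem sizes and numerical choices

The test suite uses compact banks (N ≤ 14 with 40 curve points for
recovery and population tests; N ≤ 10 with 20 points for the 200-run
permutation-calibration simulation) — large enough to contain the
generating member and to exercise every code path, chosen to keep the
suite fast on one core. The benchmark curves for N = 4 and N = 10 are
always swept at the full 200-point resolution. Parameter-recovery checks
use 25 seeded runs against 3-standard-error bands from the expanded-set
WLS.

Known limitations: the solver's capped iterations near merge transitions
leave a handful of flagged curve points per sweep (their coordinates are
accurate to well below the 0.005-bit benchmark tolerance); the bank JSON
format stores dense encoders and grows to ~100 MB at 50 × 200 (use it as
a run artifact, not an archive format); and `population_maps` assumes all
grids came from the same bank.
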