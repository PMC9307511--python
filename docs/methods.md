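# Methods

## Model and procedure

The package detects structurally variable regions (SVRs) between two
cellular conditions from per-nucleotide structure-probing (SP)
reactivities. The analysis has two stages.

**Normalization** makes reactivities comparable across conditions without
assuming any parametric reactivity distribution. Step 1 winsorizes each
replicate at its 5th and 95th empirical percentiles (linear-interpolation
quantiles) and rescales to [0, 1]; a profile that is constant after
clipping maps to all zeros (it carries no structural signal). Step 2
quantile-normalizes within-condition replicates; with unequal non-missing
counts, each replicate's sorted values are replaced by the mean empirical
quantile function of all replicates evaluated at that replicate's plotting
positions, which reduces to columnwise means of sorted values when counts
are equal. Step 3 fits `log r̄_A ~ log α + β log r̄_B` over a structurally
invariant pivot set S by Huber M-estimation (tuning constant 1.345 times a
MAD-based scale, IRLS to coefficient change < 1e-8 or 50 iterations —
statsmodels RLM) and extrapolates the fitted map to all positions;
condition A is the unchanged reference. Pivot positions require both
condition means above a positivity floor of 1e-3 before taking logs; below
the floor the fitted map is extended linearly through the origin so zeros
stay zero, the map stays monotone, and an identity fit transforms exactly
identically.

**Scan.** Positional p-values come from two-sided Wilcoxon rank-sum tests
on the pooled per-condition reactivities in a radius-2 window around each
position (window truncated at transcript ends; a position is testable when
both pooled samples have at least 3 non-missing values). The test is exact
(full enumeration of the rank-sum distribution) when both pooled samples
have at most 10 values and no ties, and otherwise uses the normal
approximation with tie and continuity corrections; identical pooled
multisets give p = 1, keeping p in (0, 1]. Candidate regions of all lengths
L_min..L_max (defaults 1 and 100 nt) are scored with
Q(R) = (−Σ log p_j)/√|R| and calibrated against a Monte-Carlo null (below);
significant regions are reported greedily by descending Q (ties: longer
region, then smaller start) subject to non-overlap, each with the add-one
Monte-Carlo p-value (1 + #{T_b ≥ Q})/(B + 1). Family-wise error is
controlled per transcript; `--global` additionally Bonferroni-corrects
across transcripts. For top-k evaluation curves, positions inside called
SVRs rank first (by covering-region Q, then positional p), then remaining
positions by positional p; with no calls the ranking is ascending
positional p.

## The Monte-Carlo null

The null hypothesis is "no structural difference", under which each
positional p-value is (marginally, up to rank-test discreteness)
Uniform(0,1). The naive null that draws the p_j independently Uniform(0,1)
and takes the max of Q over candidate regions is **anti-conservative**
here, because neighboring positional tests share most of their window
(radius 2 means adjacent windows overlap in 4 of 5 positions), making
neighboring p_j strongly positively correlated; region sums of −log p then
have far heavier tails than under independence. Measured on simulated
negative controls, the independent-uniform null yields a family-wise error
rate of ~0.34 at a nominal 0.05 even though the marginal p_j are well
calibrated.

The default ("windowed") null therefore simulates at the reactivity level:
for each of B null transcripts, i.i.d. continuous values are drawn for the
actual replicate counts (n_A, n_B), the windowed rank-sum p-value is
recomputed at every position with the same radius (exact, tie-free, via a
cached subset-sum recursion for the rank-sum distribution), and the maximum
of Q over all candidate regions is recorded. This reproduces the
window-overlap dependence exactly and leaves the null independent of the
observed data, so it can be cached: one null serves all transcripts whose
lengths fall in the same geometric bin (±5%, simulated at the bin's upper
edge, which errs conservatively) with the same replicate counts. Two
alternative modes are provided: `uniform` (the literal independent-uniform
null, useful for sensitivity analysis and for the closed-form checks it
admits) and `permutation` (replicate-label shuffling, which retains
*replicate-level* dependence too but has very low granularity with few
replicates). Missing positions in real data reduce the number of candidate
regions relative to the complete-data null, which is conservative.

## Pivot screening

The data-driven pivot is found by screening: positional rank-sum p-values
are computed on Steps-1-2 data, positions with p < `screen_p` are excluded,
the transform is fitted on the remainder, condition B is transformed, and
the screen repeats on the transformed data until the set changes by at most
1% of testable positions or `max_iter` (5) rounds. The default `screen_p`
is 0.05, deliberately strict: the screen exists only to keep strongly
differential positions out of S, since the Huber loss already downweights
moderate contamination (20% contamination moves β̂ by < 0.1 in the test
suite). A loose screen (e.g. 0.25) excludes a quarter of null positions —
spatially clustered by the windowed test and concentrated in particular
reactivity ranges — which biases the extrapolated fit and measurably
inflates the scan's false positive rate on negative controls. A
user-supplied pivot (prior knowledge) bypasses screening entirely. The
screen is windowed, so it is not invariant to position permutation; the
rest of the pipeline is.

Screening presupposes that reactivities are positionwise correlated between
conditions (shared underlying structure); the log-linear fit is
uninformative if the two conditions' profiles are independent noise.

## Simulator

The simulator emulates the conformational-ensemble view of RNA structure:
a transcript is a mixture of K = 10 pairing-status conformations whose
weights differ between conditions.

- *Conformations*: the reference conformation is a symmetric two-state
  Markov chain along the sequence (mean run length 6 nt, about half of
  positions paired), giving helix-like blocks. Each other conformation
  copies the reference and flips its status inside an independent sparse
  set of deviation blocks (geometric runs, mean 6 nt, stationary density
  0.2). True SVRs are the maximal runs where conformations 1 and 2
  disagree, so they cover ~20% of positions on average, with lengths from
  1 nt to tens of nt. This replaces thermodynamic-ensemble sampling by an
  external folding engine; it reproduces the statistically relevant
  features (blocky pairing, high inter-conformation similarity, variable
  SVR lengths) but not sequence-specific energetics.
- *Reactivities*: conditional on pairing status, values are drawn from
  platform-style distributions — two SHAPE-like gamma pairs (low-mean
  paired, high-mean unpaired) and an icSHAPE-like zero-inflated beta pair
  on [0, 1]. These parameterizations are synthetic stand-ins styled after
  the named platforms, not fitted models; any `ReactivityModel` can be
  plugged in, including point masses for closed-form checks.
- *Conditions and replicates*: 90% of the weight goes to conformations 1
  and 2 — (w1, w2) = (0.4, 0.5) vs (0.5, 0.4) at low signal, (0.3, 0.6) vs
  (0.6, 0.3) at medium, (0, 0.9) vs (0.9, 0) at high, and identical
  weights for the "null" level used in negative controls — and the
  remaining 10% is split uniformly at random over conformations 3..10,
  shared between conditions. Each replicate perturbs (w1, w2) with
  N(0, 0.1²) noise, clips to [0, 1] and renormalizes (how invalid noisy
  weights are handled is a package choice). Observed reactivities mix
  fresh conformation-level draws per replicate and position; independent
  draws avoid artificial replicate correlation, and draw-sharing across
  replicates is the main alternative a real ensemble might induce.

What passing tests on these simulations show: calibration and power of the
statistical machinery under a plausible generative model. What they do not
show: robustness to sequence-dependent probing biases, coverage-driven
missingness patterns, or platform-specific reactivity distributions beyond
the built-in families.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| radius r | 2 nt | positional test window half-width |
| L_min, L_max | 1, 100 nt | candidate region lengths |
| alpha | 0.05 | per-transcript family-wise level |
| B | 1000 (500 in the acceptance study) | Monte-Carlo null samples |
| min_obs | 3 | smallest testable pooled sample |
| screen_p | 0.05 | pivot screen threshold |
| min_coverage, min_rt | 10, 2 | count filters (positions / transcripts) |
| K, mean_run, noise_sd | 10, 6, 0.1 | simulator ensemble parameters |

Degenerate inputs: all-missing profiles are rejected; constant profiles
winsorize to zeros; zero control coverage yields missing (not 0 or ∞)
reactivity since the position carries no exposure information; a
degenerate pivot predictor (zero variance) falls back to a pure depth
offset (β = 1, log α from medians). Ties in call ordering break toward
longer regions, then smaller start. All randomness descends from a single
seed; stage-specific streams are derived from (seed, stage name), and
Monte-Carlo nulls are seeded per length bin, so results are reproducible
and independent of transcript processing order.

Problem sizes in the shipped studies — 200 negative-control runs of one
100–300-nt transcript with 2–4 replicates and B = 500, and 20 seeds per
signal level for the power study — are the package's chosen desk-scale
defaults; all sizes scale up through the configuration.

## Known limitations

- The windowed null assumes within-condition values are exchangeable across
  positions given the window geometry; replicate-level systematic effects
  beyond what quantile normalization removes are not represented in it
  (the permutation mode is the diagnostic for that).
- With a single replicate per condition, quantile normalization is an
  identity and the positional test has little power at radius 2.
- The rank test is platform-agnostic by design; when the reactivity
  distribution is known, a parametric positional test would gain power.
- The fitted between-condition transform is global per run;
  position-dependent depth or signal-to-noise distortions are corrected
  only on average.
- Evaluation treats annotation intervals as exhaustive truth; partially
  annotated transcripts bias precision downward.
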