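# Methods

## Learning model

The Rescorla-Wagner rule is implemented exactly as the recurrence
δ_t = R_t − V_t, V_{t+1} = V_t + α·δ_t with learning rate α ∈ [0, 1] and
initial value V_1 = v0. The default v0 = 0 corresponds to an agent with
no prior reward expectation; the classically quoted seven-trial trace for
the schedule [1,0,0,1,1,1,0] at α = 0.5 is only consistent with V_1 = 0.
No rounding is applied internally — the widely quoted two-decimal display
of that trace (…, 0.43, 0.21, −0.89) is a truncation of the exact values
(…, 0.4375, 0.21875, −0.890625), and tests compare accordingly. A
per-trial-type α mapping is accepted for designs with stimulus-specific
learning rates; each trial type then tracks its own predicted value.
Temporal-difference learning with within-trial time steps, and fitting α
to behaviour, are out of scope.

## Regressor construction

Events are rendered on a fine internal grid (0.1 s) as sticks
(zero-duration) or boxcars, convolved with a canonical double-gamma HRF —
gamma-density peak (shape 6, unit dispersion, mode ≈ 5 s) minus a 1/6
undershoot (shape 16), sampled on [0, 32] s and rescaled to unit peak so
event modulations carry the amplitude — then truncated to the series
length and decimated to the output interval (default 1 s). The fine
internal grid avoids onset-quantization artifacts; unit-peak scaling is a
convention only, since regressors are z-scored before fitting.

**Modulation centering.** Parametric modulation vectors are mean-centered
per event set before convolution (the convention of standard SPM-style
parametric modulators), except that constant vectors — plain onset
regressors — are left untouched. This matters: with centered modulations
and well-separated events (gaps ≥ 25 s), the Pearson correlation between
two convolved regressors equals the Pearson correlation of their
modulation vectors (0.89 in the reference scenario); with raw stick
heights it instead approaches the *uncentered* cosine (≈ 0.72), because
the onset-locked response common to both regressors acts as a shared
offset pattern.

**Standardization and orthogonalization.** z-scoring uses the population
(divide-by-n) standard-deviation convention, making small worked examples
exact. Orthogonalization residualizes the mean-centered target against
the mean-centered bases by least squares, so a zero dot product is a zero
Pearson correlation; the output is deliberately *not* re-standardized,
which preserves the identity between the orthogonalized regressor's beta
and its beta in the non-orthogonalized joint model (the semipartial /
Frisch-Waugh identity the second comparison approach relies on). A target
within the span of its bases (residual sd < 1e−12) is rejected as
degenerate.

## GLM layer

Ordinary least squares via pivoted QR with a rank check at relative
tolerance 1e−10 on the R diagonal; rank-deficient designs raise an error
naming the collinear columns rather than silently pseudo-inverting —
near-collinearity is the package's whole subject, and silent solutions
would mask it. `k` counts all columns including the intercept, so
equal-complexity comparisons stay equal-k. The log residual variance is
ln(RSS/n) with no degrees-of-freedom correction, matching the AIC/BIC
forms n·ln(RSS/n) + 2k and n·ln(RSS/n) + k·ln(n); for equal k and n the
three orderings coincide by algebra, which the tests assert. Information
criteria on a zero-RSS fit raise (they would be −∞, signalling noise-free
or overfitted input). GLS/prewhitening, autocorrelation modelling and
group-level inference are out of scope.

## Comparison semantics

All three approaches reduce to a signed margin, statistic_A −
statistic_B (betas, or negative log residual variance), with an explicit
tie band (default 1e−6 on the standardized-beta scale) — the equivalence
of the approaches holds only away from ties, so ties are reported as such
rather than broken arbitrarily. Winners are compared on signed betas by
default, matching positive-signal designs; `use_abs` switches to
magnitudes for signals of unknown sign. At single-series scale the
comparison is between point estimates; a statistical flavour is obtained
by replicating over simulation seeds (as the acceptance suite does) or
over voxels. When the candidates share more than half their variance
(r² > 0.5) the report carries a caveat: which model "deserves" the shared
variance is a matter of prior knowledge, not of these statistics.

## Simulator

A region is y = w_A·A + w_B·B + ε with A, B the z-scored candidate
regressors, so weights are interpretable as relative standardized
contributions, and ε white Gaussian with sd equal to `noise_sd` times the
population sd of the mixed signal. Defaults reproduce the reference
two-region scenario: 200 s at 1 Hz, seven zero-duration reward events at
onsets 10 + 27k s (k = 0…6; the spacing is a documented configuration
choice giving gaps ≥ 25 s, under which the regressor correlation equals
the modulation correlation), RO modulations [1,0,0,1,1,1,0], RPE
modulations from the RW trace at α = 0.5, Region A weighted (0.8, 0.2),
Region B (0.2, 0.8), `noise_sd` = 0.2. Per-region noise streams derive
deterministically from one root seed (child seeds kept below 2³¹), and
the provenance block regenerates a dataset bit-identically.
`tile_volume` tiles the two regions into 3×3×3 voxel blocks (with a
one-voxel gap) of a small 4-D volume with independent per-voxel noise, to
exercise the voxelwise path without external data.

What the simulator emulates: event-locked hemodynamic responses, known
mixtures, and white noise. What it does not: physiological drift and
autocorrelated noise, inter-subject variability, spatial smoothness, and
hemodynamic variability across regions. Passing tests therefore
demonstrate the statistical identifiability of the winner under the
stated conditions, not robustness to fMRI noise structure.

## Validation sizes

The property and acceptance tests use the 200-sample reference series;
replicated checks run 100 seeds for winner recovery at `noise_sd` = 0.2
and 100 random mixtures (weight gap ≥ 0.2, noise sd ≤ 0.5) for
cross-approach agreement — sizes at which every suite run completes in
seconds while the binomial margins on the ≥ 95% claims remain meaningful.
Solver correctness is checked against an independent pseudo-inverse
oracle on 50 random problems and by exact weight recovery at zero noise.

## Interfaces

Events follow the BIDS `events.tsv` dialect (tab-separated `onset`,
`duration`, `trial_type`, optional `modulation`, seconds; a missing
modulation column defaults to 1). Series are plain TSV with a `time`
column; volumes are NIfTI-1 with a binary mask. A YAML config names
exactly two candidate models, each either a direct modulation column or a
Rescorla-Wagner derivation (α, v0) from a reward column. Reports are
written as sorted-key JSON plus a flat TSV (one row per region ×
approach); the CLI (`orthoglm simulate | compare | voxelwise`) is a thin
wrapper over the library and is fully deterministic given config + seed.
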