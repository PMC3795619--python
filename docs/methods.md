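# Methods

## Growth functions

Four mean curves for disc width at age are implemented (`models.py`):
three-parameter von Bertalanffy (VBGF), two-parameter von Bertalanffy
(2VBGF) with size at birth fixed, logistic, and Gompertz. All are
parameterised so that the curve rises monotonically to the asymptote
`w_inf`; the three size-at-birth forms satisfy `W(0) = w0`. Two forms
deserve a note:

* **Gompertz** is the size-parameterised form
  `W(t) = w_inf * exp(ln(w0/w_inf) * exp(-k t))`, chosen because it shares
  the `W(0) = w0`, `W(inf) = w_inf` boundary behaviour of the other
  size-at-birth models.
* **Logistic** is
  `W(t) = w_inf*w0*e^{kt} / (w_inf + w0*(e^{kt}-1))`. Its rate constant is
  on a different scale from the von Bertalanffy `k` (fitted logistic rates
  are typically an order of magnitude larger) and must not be compared
  across models.

The 2VBGF is the VBGF with `t0 = ln((w_inf-w0)/w_inf)/k`; a property test
checks the two agree to 1e-9 across random parameter draws.

`w0` is an input, not an estimate, for the 2VBGF and the Bayesian stage:
size at birth is generally well documented for rays, and the default per
species is the minimum observed disc width of that species' sample (25,
17, 36.5 and 14 cm for the four presets).

## Ford–Walford initialisation

Starting values for `(w_inf, k)` regress mean size at age `t+1` on mean
size at age `t` over consecutive integer ages; under von Bertalanffy
growth slope `= e^{-k}` and `w_inf = intercept/(1-slope)`. Non-integer
ages (the half-year edge-band convention) are binned to the nearest
integer and averaged first. A slope outside (0, 1) — flat, noisy or
diverging sizes — is a flagged failure and callers fall back to
`1.2 × max observed size` and `k = 0.2` (or the Beta-prior mean in the
Bayesian stage).

## NLS fitting and AICc selection

Each model is fitted by bounded least squares (`scipy.optimize.least_squares`,
trust-region reflective) from the Ford–Walford start with 5 jittered
restarts, keeping the best residual sum of squares. Bounds:
`w_inf ∈ [max observed size, 5×max]`, `k ∈ [1e-4, 50]`,
`t0 ∈ [-10, min age]`, and for logistic/Gompertz `w0 ∈ [1e-3, max observed]`.
The lower bound on `w_inf` stabilises data-poor fits; when a sampling
frame reaches the asymptote, observations can pile above the true
`w_inf` and the bound then binds — a known trade-off accepted because the
method targets small, incompletely sampled collections.

The three-parameter models estimate their third parameter (`t0`, or `w0`
for logistic/Gompertz); the 2VBGF holds `w0` fixed. Parameter counts for
AICc include the error variance: `p = 3` for 2VBGF, `p = 4` otherwise.
AICc uses the least-squares form `n ln(RSS/n) + 2p + 2p(p+1)/(n-p-1)`
(the likelihood form differs only by an additive constant shared across
models, so rankings are unchanged). Δ ≤ 2 is labelled "highest" support;
AICc ties within 1e-9 rank the more parsimonious model first. A perfect
fit (RSS = 0) has no finite least-squares AICc and is reported as an
error rather than ranked.

## Bayesian 2VBGF estimation

The likelihood is Gaussian and additive:
`W_i ~ Normal(2VBGF(t_i; w_inf, k, w0), sigma2)`. The posterior is the
ordinary product of likelihood and priors — the informative priors act as
the penalty that stabilises data-poor estimation; no extra penalty term
is used. Priors:

* `w_inf`: lognormal with log-scale sd 0.5, location `ln 77 − 0.5²/2` so
  the **natural-scale mean is exactly 77 cm**. The natural-scale mean is
  the reading adopted for "mean 77 cm with sd 0.5 in log space"; the
  alternative (77 cm as the log-scale location, i.e. the median) is one
  config flag away (`log_location_mean=True`).
* `k`: Beta(21.9, 162.3) on (0, 1) yr⁻¹ — mean ≈ 0.119, sd ≈ 0.024, a
  deliberately tight prior pooled from published dasyatid estimates. It
  restricts `k < 1`; a warning is emitted when an NLS `k` estimate
  exceeds 1, since the Bayesian model truncates it.
* `sigma2`: inverse-Gamma(0.01, 0.01), effectively non-informative.

Sampling is random-walk Metropolis–Hastings on
`(log w_inf, logit k, log sigma2)` with the Jacobian correction, all three
coordinates proposed jointly from independent Gaussians. Proposal scales
start at (0.05, 0.10, 0.20) and are multiplied by
`exp(rate − 0.30)` every 500 burn-in iterations (clipped to
[1e-5, 5]), targeting 20–40 % acceptance; adaptation is frozen at the end
of burn-in so the retained chain satisfies detailed balance. The chain is
initialised at the Ford–Walford point clipped into the prior support with
`sigma2` at the residual mean square. Chains are reproducible bit-for-bit
given (seed, config, data): all random numbers are pre-drawn from one
`numpy` PCG64 generator.

Presets: `paper` (2 M iterations / 100 k burn-in / thin 100 → 19 000
retained draws) mirrors the reference analysis; `desk` (200 k/20 k/20,
9 000 draws) reproduces its summaries to well within Monte-Carlo error in
a few seconds and is the workflow default; `sim` (50 k/5 k/10) is for
replicated simulation studies. Posterior summaries are the median and
central 95 % credibility interval.

**Validation.** The sampler is checked against a brute-force
grid-integration posterior (240 × 240 × 200 lattice over
`(w_inf, k, sigma2)`) on an 8-point dataset — medians agree within 2 % —
and against the priors themselves in a zero-information limit (variance
pinned at 1e8), where posterior and prior quantiles coincide within
Monte-Carlo error.

## Geweke diagnostic

`z = (mean_A − mean_B) / sqrt(sVar_A/n_A + sVar_B/n_B)` comparing the
first 10 % (A) with the last 50 % (B) of the retained chain. Each
segment's long-run variance is the spectral density at zero estimated
with a Bartlett (Newey–West) window at the standard automatic lag
`4(n/100)^{2/9}`. On 1000 iid-normal chains of length 5000 the
|z| > 1.96 rate is ≈ 5–6 % (calibration test); a deterministic trend
yields |z| ≫ 10.

## Precision indices

Per animal `j` with `R` readers: `APE_j = (100/R) Σ_i |x_ij − x̄_j|/x̄_j`
and `CV_j = 100 sd_j/x̄_j` with the sample (R−1) standard deviation;
overall IAPE and CV are means over animals. On two-reader data
`CV_j = √2 · APE_j` identically. The per-reader columns are an
interpretation (the classical indices are the overall ones): reader `i`'s
mean percent absolute deviation from the per-animal mean, the CV variant
scaled by `sqrt(R/(R−1))` for consistency with the sample-sd convention.
Consensus ages require at least two agreeing readers; with ≥ 4 readers a
tie between two modal values is unresolved. Readability-3 (unreadable)
animals are excluded before any fitting.

## Synthetic data

Templates draw ages uniformly on the species' observed range, rounded to
the half-year grid (mirroring the edge-band +0.5 yr convention), and
sizes from the 2VBGF mean plus additive Gaussian noise truncated to
positive values by redrawing. Default noise sd is 4 % of `w_inf` —
residual scatter consistent with published size-at-age plots for these
species — and 3 % is used in the parameter-recovery runs. The four
presets use each species' published Bayesian posterior medians as
generating values, the observed age ranges (1–25, 1.5–13, 1–27, 1–11 yr),
minimum observed sizes as `w0`, and the field sample sizes (19, 34,
32, 40).

What the generator does *not* emulate: ageing error (ages are treated as
known in the growth stage), gear selectivity beyond the explicit
truncation schemes, sex differences, or non-Gaussian residuals. Passing
recovery tests therefore shows the estimation machinery is correct and
well calibrated under the assumed model, not that the model captures
every feature of real field data.

The well-represented design places `m` observations at each of `A`
integer ages (default 20 × 10 = 200 records); data-poor subsampling
either draws `n` at random or first removes the oldest (or youngest)
third of the age classes — parameterised stand-ins for incomplete field
sampling. Reader matrices give each reader a ±1-band miscount with
probability ε and draw readability scores with proportions 50:75:45.

## NLS-vs-Bayes simulation study

For each scenario × replicate: generate the full design, subsample, fit
both estimators, record the NLS point estimate and the Bayesian posterior
median. Aggregates are bias, RMSE and the across-replicate spread of
point estimates (the headline uncertainty measure for NLS; the Bayesian
rows also carry mean credibility-interval width). `RMSE² = bias² +
spread²` holds exactly (population sd), which the tests cross-check.
Replicates use the `sim` MCMC preset to keep 50-replicate experiments
around a minute. In the age-truncated n = 15 scenario the Bayesian RMSE
for `w_inf` is reliably below the NLS RMSE — the informative prior
anchors the asymptote when old animals are missing; in the data-rich
design both methods are nearly unbiased.

## Problem sizes

Defaults chosen as desk-scale analyses: recovery runs use n = 500
records and the 200k/20k/20 chain (about 2 s each); the comparison study
50 replicates of 50k-iteration chains; the grid oracle a 240 × 240 × 200
lattice. The reference 2M/100k/100 chain is available as the `paper`
preset.

## Known limitations

* The Beta prior restricts `k` to (0, 1); species with genuinely faster
  von Bertalanffy rates need a rescaled prior (out of scope here).
* The `w_inf ≥ max observed size` NLS bound biases fits when a sample
  densely covers the asymptote (see above).
* Per-reader IAPE/CV columns are an interpretation; published per-reader
  values computed from unavailable raw reads cannot be reproduced
  exactly.
* No hierarchical sharing of priors across species, no alternative
  samplers, no model averaging.
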