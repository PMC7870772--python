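# Methods

`cppddm` implements a hierarchical Bayesian analysis of two-choice motion
discrimination: response time and choice are decomposed with a
four-parameter drift-diffusion model, trials are screened with an EWMA
fast-guess filter, response-locked EEG is decomposed into reliable
components whose ramp slopes enter the model as drift-rate covariates, and
competing covariate structures are compared by DIC.  This note documents
the models, the numerical choices, and what the bundled synthetic data can
and cannot establish.

## The diffusion model

A decision is a Wiener process with unit diffusion coefficient between
absorbing boundaries at 0 and α (boundary separation, evidence units),
starting at βα (β ∈ (0,1), relative bias toward the upper boundary) with
drift δ (evidence/s).  An 'up' response is absorption at the upper
boundary; observed RT is first-passage time plus non-decision time τ (s).
On trials whose stimulus moves down the drift is −δ, so δ is always the
rate of accumulation of *correct* evidence while β remains the bias toward
'up'.  Between-trial variability parameters (sv, st, sz) are deliberately
excluded: they are weakly identified at the trial counts this design
yields.

The first-passage density is evaluated through both classical series
expansions of the unit-boundary density — the small-time sum over image
charges and the large-time sine series — choosing whichever needs fewer
terms at a term-magnitude tolerance of 1e−29.  The two expansions agree to
better than 1e−6 relative at the switch point (tested by locating the
crossover by bisection).  Trial simulation is Euler–Maruyama at dt = 1e−4 s
with a Brownian-bridge boundary-crossing correction inside each step;
without the correction the zero-drift mean decision time is biased upward
by ≈ 2.5% at this dt, with it the residual bias is below Monte-Carlo noise
at n = 100,000 (the package's standard calibration size).

## Trial screening

Structural exclusions remove catch trials, responses at or beyond the
2.5 s deadline, and the excluded lowest-coherence condition.  The EWMA
filter sorts each participant's trials by RT (stable ties by trial index)
and runs an exponentially weighted moving average of accuracy
(λ = 0.1, c₀ = 0.5, σ₀ = 0.5, L = 1.5) against its upper control limit;
the first sorted trial at which c_s strictly exceeds UCL_s marks the
fastest RT at which responding is credibly above chance, and all faster
trials are discarded (the cutoff trial itself is kept; both choices are
configurable, as is a "last trial below the limit" cutoff variant).
Participants retaining < 60% of trials, or with accuracy significantly
below 0.5 (one-sided binomial test at α = 0.05 — our operationalisation of
"substantially below chance"), are dropped.

A property worth knowing: with 20% injected fast guesses the first-crossing
rule removes ≈ 95% of them in the median replicate, but a lucky run of
correct guesses (they are Bernoulli(0.5)) crosses the λ = 0.1 / L = 1.5
limit early in roughly a quarter of replicates, after which all later
guesses are retained; the aggregate removal rate is therefore ≈ 0.78, and
it *decreases* with trial count.  The "last trial below" variant removes
98.5% of guesses but also ≈ 18% of genuine trials.

## Hierarchical model and priors

Participant-level parameters are truncated-normal draws around group
means: α ∈ [0.2, 4], β ∈ [0.001, 0.999], τ ∈ [0.1, 2], δ ∈ [0, 8].
Condition (coherence) effects on drift are fixed effects on the
standardized scale: δ_pc ~ TN(μ_δ + σ_ε[(Qθ)_c + Σ_j b_j z_j(p)], σ_ε),
where Q is the orthonormal sum-to-zero projection of k−1 free effects θ
(so condition offsets always sum to zero) and z_j are z-standardized
participant covariates (age, EEG slopes).  Covariates on α or τ shift the
group mean by σ_α/τ · Σ b_j z_j(p) in the same way, so all reported
weights are standardized.  The residual variance reported for a parameter
carrying covariates is the posterior mean of its squared group SD — the
spread left after the regression shifts the mean.

Group-level priors are informative and centred on typical values from
parameter surveys of simple two-choice tasks: μ_α ~ N(1.0, 0.5²),
μ_β ~ N(0.5, 0.125²), μ_τ ~ N(0.4, 0.3²), μ_δ ~ N(2, 1.5²), each truncated
to its parameter's bounds; σ_α, σ_β, σ_τ, σ_ε ~ half-normal(0.5, 0.125,
0.3, 1.0).  The standardized weights carry Zellner–Siow mixture-of-g
priors: θ_n, b_j ~ N(0, g) with g ~ inverse-gamma(1/2, 1/2), one g for the
condition effects and one per parameter's covariate block (covariates are
unit variance, so the scale is 1).

The model family (models 1–12) mirrors the covariate structures of
interest: model 1 has none; models 2–5 place age on subsets of {δ, α, τ};
models 6–8 place the EEG component slopes on δ; models 9–12 combine age
and EEG covariates.

## Sampling

The sampler is adaptive Metropolis-within-Gibbs.  Participant-level
parameters get Gaussian random-walk updates inside a compiled kernel with
the per-(participant, condition) log-likelihood cached; group-level
scalars get random-walk updates against their conditional densities
(truncation normalisation included — it depends on the group parameters);
the g scales are conjugate inverse-gamma Gibbs draws.  Proposal scales
adapt toward 35% acceptance in batches of 50 during burn-in only, keeping
the post-burn-in chain Markovian.  Because a group SD and its participant
block form a funnel — acute for the starting point, whose block barely
informs the likelihood — every sweep also makes an interweaved scale move
(propose σ′ = σ·e^ε and rescale all participant deviations jointly; the
truncated-normal kernels cancel against the Jacobian).  This move cut the
worst-case R̂ on weak-covariate fits from ≈ 2.2 to ≈ 1.03 in our checks.
Starting values are uniform over the admissible ranges, with non-decision
time capped below each participant's fastest RT.  Chains are
seed-deterministic (chain c uses SeedSequence([seed, c])).

Deviance (−2 log likelihood at the participant-level parameters) is
recorded per retained draw; DIC = mean deviance + p_D with
p_D = mean deviance − deviance at the posterior means of the
participant-level parameters (the plug-in focus JAGS uses).  Convergence
is monitored with the classic Gelman–Rubin R̂.

Problem sizes: production settings are 3 chains × 54,000 samples with
4,000 burn-in and thinning 5 (10,000 retained per chain).  The bundled
analyses and the acceptance checks use 3 chains × 1,500–2,100 sweeps after
500–600 burn-in sweeps; a pilot recovery study showed group-level
posterior summaries stable at that length for the cohort sizes used
(40 × 3 × 90 trials), and all recovery conclusions below refer to those
sizes.

## EEG pipeline

Cleaning follows a fixed order: per-trial median DC correction; electrode
outlier detection (fraction of |amplitude| samples above the pooled 97.5th
percentile ≥ 15%) with interpolation by the mean of the 6 nearest
neighbours (4 on the montage perimeter); EOG regression (OLS per
electrode); a second, per-trial percentile pass that removes (sets
missing) misbehaving electrodes within a trial; ±4 SD transient censoring;
average reference; baseline subtraction (first 100 ms of the epoch for
purely response-locked data — a stand-in for the pre-evidence baseline the
full recording design would use); and rejection of trials with ≥ 19 bad
electrodes.  Missing data are NaN throughout and never decrease through
the censoring stages.

Reliable components analysis maximises w′R_xy w / w′R_xx w, with R_xy the
cross-covariance averaged over all ordered pairs of distinct trials
(computed in O(trials) via the sum identity, then symmetrised) and R_xx
the pooled within-trial covariance.  The generalised eigenproblem is
solved in a principal-component basis of R_xx capturing 99% of its
variance (configurable rank); explained reliability fractions are
normalised by the sum of positive eigenvalues; components are oriented so
the grand-average projection at the response is positive.  Missing samples
contribute zero to cross-products with count-based normalisation
(approximate pairwise-complete); projections through weights rescale by
the remaining squared-weight mass when electrodes are missing.

Regression windows: component 1's window ends at the mid-latency of the
positive peak (mean of the two 90%-amplitude crossing latencies, linear
interpolation between samples) and starts at the latest pre-end crossing
of 30% of the waveform's amplitude at the mid-latency; component 2's
window runs between the mid-latencies of its negative and positive peaks
found within −600..100 ms.  Both are computed on group grand averages;
participant slopes are OLS fits (µV/s) over the group window and enter
the model z-standardized.  On the small synthetic cohorts the pipeline
smooths grand averages (20 ms FWHM Gaussian) before peak finding and falls
back to fixed windows spanning the generative ramp segments when detection
fails; at realistic grand-average sizes (tens of thousands of pooled
trials) neither aid is needed.

## Synthetic data: what it emulates and what it does not

Behaviour is generated from exactly the hierarchical model above (child
regime: μ_α = 1.5, μ_β = 0.5, μ_τ = 0.45 s, μ_δ = 2.0 with condition
offsets ±0.7 SD; adult regime: narrower boundaries, faster non-decision
time, higher drift), with a configurable standardized age effect
(default studies use age→δ = 0.45, age→α = −0.10) and a fast-guess
contaminant process (uniform RT on [0.15 s, participant's 10th RT
percentile], chance accuracy).

EEG epochs are two spatial components times response-locked waveforms plus
rank-8 spatially correlated Gaussian noise (5 µV).  Component 1 is a
centro-parietal pattern with a linear ramp from a per-participant onset
(uniform −450..−300 ms) peaking at the response; its slope is
10 + 4·mean-drift + N(0, 3.2²) µV/s, making the slope–age correlation
≈ 0.3 and the implied standardized drift weight ≈ 0.43 in the default
child cohort.  Component 2 is an occipital pattern with a weaker biphasic
waveform (trough −250 ms, positive peak −20 ms, asymmetric lobes) whose
central rise is 12 + 1·mean-drift + N(0, 6²) µV/s (implied drift weight
≈ 0.06–0.10).  Each participant's biphasic waveform is orthogonalised in
time against their ramp, and component 2 is kept ≈ 8× weaker than
component 1: both properties are needed for a reliability decomposition to
separate the sources (a temporal cross-covariance mixes the generalised
eigenvectors systematically; near-equal eigenvalues mix them under
finite-sample noise).  Trial-to-trial gain jitter (lognormal, sd 0.2)
keeps reliability below 1.

The generator does not emulate: ocular or movement artefacts as physical
sources (EOG traces for the regression tests are synthetic), volume
conduction from dipoles, skull-conductivity differences across age,
stimulus-locked potentials, attentional lapses, or the deadline effects
that made the hardest coherence condition misfit.  Passing tests therefore
establish that the estimation machinery recovers known structure under the
model's own assumptions — not that the model is adequate for any
particular real dataset.

## Known limitations

- The Metropolis-within-Gibbs sampler is slower-mixing than gradient-based
  samplers; the defaults compensate with thinning and long chains, and R̂
  should always be checked (the pipeline's `--strict` flag aborts above
  1.05).
- DIC differences of a few units are unstable under sampling variation;
  the comparison table should be read together with the residual
  variances, as in the bundled analysis.
- The EWMA filter's aggregate fast-guess removal is capped near 78% under
  the first-crossing rule (see above); this is a property of the method at
  λ = 0.1, L = 1.5, not of the implementation.
- Pairwise-complete covariance handling in RCA is approximate under heavy
  missingness; upstream trial rejection keeps missingness light.
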