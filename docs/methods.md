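# Methods

`wmeeg` predicts a person's working-memory ability from resting/task EEG.
This note documents the models the package implements, the choices that
were genuinely open, and what the synthetic study generator does and does
not emulate.

## Problem and labels

Subjects perform a card-pairing memory task; the time they need is the
behavioural outcome. Performance is expressed as a z-score of the inverse
completion time over the cohort, `z = (x − μ)/σ` with `x = 1/t`, so a
faster subject ranks higher and the score is comparable across people.
The scaler uses the population (divide-by-n) standard deviation; with
standardized labels a trivial mean predictor has held-out MSE ≈ 1, which
is the natural reference point for every model below. A cohort of one has
no ranking and receives z = 0 by convention.

## Features

Each channel contributes three band power ratios,

    BPratio_b = BP[b] / BP[1–44 Hz],   b ∈ {alpha 8–13, beta 13–30, gamma 30–44 Hz},

computed from the Hann-windowed periodogram of the whole segment (no
Welch averaging). Band edges are half-open `[lo, hi)` so the printed
bands, which share endpoints, stay disjoint — 13 Hz belongs to beta only.
With the 10-channel 10-10 montage (Fpz, Fz, F7, F8, T7, T8, Cz, Pz, Poz,
Oz) a recording maps to a 30-component channel-major feature vector.
Ratios are amplitude-invariant, so gain differences between channels and
sessions drop out.

Preprocessing before feature extraction runs four stages in fixed order:
bad-channel removal (non-finite samples or variance below 1e−12),
peak-noise thresholding (default 100 µV; out-of-range samples are
replaced by linear interpolation between in-range neighbours rather than
rejecting the trial), average re-referencing, and a centred moving-average
filter (default width 5 samples, which at 1000 Hz leaves the gamma band
largely intact). Every stage can be disabled; the thresholds are
configuration, not estimates.

## The working-memory model and the fuzzy layer

Two empirical regularities anchor the knowledge-based design:

1. **Energy shift.** Task onset lowers the alpha ratio and raises beta
   and gamma (engagement instead of relaxation).
2. **Performance link.** Across people, performance relates negatively to
   alpha and positively to beta/gamma.

The fuzzy transformer turns each channel's z-scored `(alpha, beta,
gamma)` triple into one degree in [0, 1] of satisfying this model,
compressing 30 features to 10. Inputs carry Low/Medium/High triangular
terms peaking at −3/0/+3 (inputs clamp to ±3, turning the outer terms
into saturating shoulders); outputs carry Low/Medium/High triangles
peaking at 0/0.5/1. Each of the 27 rules scores its antecedents for the
model (alpha Low, beta High, gamma High support it; Medium is neutral;
the opposite ends oppose) and the consequent is High at score ≥ +2, Low
at ≤ −2, Medium otherwise.

Inference uses the product t-norm, the maximum firing strength per
consequent term, **scaled** (Larsen) implication with additive
aggregation, and centroid defuzzification on a fixed 1001-point grid.
Scaling rather than clipping is deliberate: scaling preserves each
consequent term's centroid, which makes the crisp output monotone in
every input — the property the rule base encodes. Clipped, max-aggregated
output provably dips during term transitions (a shoulder triangle's
centroid moves as it is clipped), contradicting the intended monotone
surface. With this layout the neutral point (0,0,0) maps to exactly 0.5
and the extreme corners to 1/6 and 5/6 (the centroids of the outer output
terms). The exact breakpoints and rule table of the original instrument
are not recoverable; the defaults above are declared, not inferred, and
gamma participates in the inference alongside alpha and beta.

## Regressors

* **Epsilon-SVR** (the shared building block): prediction is the kernel
  expansion `f(x) = Σ (a_i − a_i*) k(x_i, x) + b`. Fitting delegates to
  scikit-learn's solver; the fitted expansion is extracted into a plain
  dataclass so prediction and JSON-text serialisation are self-contained.
  Defaults: C = 1, ε = 0.1, Gaussian γ = 1/(d·Var X). Because kernel
  width dominates generalisation here, every Gaussian-SVR stage used in
  model comparison selects (γ, C) by the same internal subject-grouped CV
  over a shared log grid (γ multipliers 0.01–1, C ∈ {1, 10, 100}) —
  uniform tuning keeps the comparison about representations, not about
  tuning asymmetries.
* **Knowledge-based FSVR**: z-scale the 30 ratios on the training set,
  apply the fuzzy transform, fit a Gaussian SVR on the 10 degrees. The
  frozen chain (scaler → rule base → SVR) is applied verbatim at predict
  time.
* **Multi-linear SVR with FCM clustering**: a Gaussian baseline SVR is
  fitted on all data; points with absolute residual strictly below
  τ = 0.5 form the clustering set; fuzzy C-means partitions it; one
  linear SVR per cluster is trained on membership-weighted samples (the
  soft analogue of hard partitions, avoiding empty clusters); prediction
  is the membership-weighted fusion of the experts — a convex combination.
  K runs over 2–10 and is selected by internal 5-fold CV with the
  one-standard-error parsimony rule (the smallest K within one SE of the
  best); exact-equality ties never occur on continuous CV curves, and the
  rule keeps flat CV regions from selecting spuriously large K. Points
  excluded from the clustering set are still predicted by the fused
  experts at test time.
* **Fuzzy logic regression**: the fuzzy layer alone, as an affine map of
  the mean per-channel degree, least-squares fitted.
* **LASSO**: L1-penalised linear regression on the standardized 30
  ratios, λ by internal CV over a log grid — the conventional sparse
  baseline.

**FCM.** Memberships use the closed-form minimiser of
`J = ΣΣ w_ij^m ‖x_i − c_j‖²` under the sum-to-one constraint; centroids
are `w^m`-weighted means. Defaults m = 2, tol 1e−6 on centroid movement,
max 300 iterations, initialisation by seeded sampling of K distinct data
points. A point coinciding with a centroid receives membership 1 there.
J is non-increasing across iterations; m → 1⁺ approaches hard k-means.

## Evaluation protocol

Method comparison uses identical subject-grouped splits for all methods
(no subject in both train and test): EEG band ratios carry a stable
individual fingerprint, and ungrouped splits would reward person
re-identification instead of ability prediction. Default protocol is
5-fold grouped CV; the replicate-study comparisons use a grouped 30%
holdout per replicate to stay cheap. Proposition statistics follow the
study's layout: the energy-shift rate is the fraction of subjects whose
trial- and region-averaged rest→task change has the predicted sign
(strict inequality, with a 1e−12 tolerance absorbing float rounding);
the performance link is a per-region, per-band simple linear regression
of z on the region-averaged ratio with a two-sided t-test on the slope.
P-values are reported uncorrected for multiple comparisons, and the
report says so. Regions: superior frontal gyrus = {Fpz, Fz}, cuneus =
{Poz, Oz}, full = all ten channels.

## Synthetic study generator

The generator exists because the original recordings are not deposited;
it emulates the study conditions so every pipeline stage is testable.

Per subject, a latent ability θ ~ N(0, 1). Log band powers per channel:

    l_b = log(base_b) + trait_b + task·s_b·effect·r_c·softplus(1 + 0.8 θ) + ε_b

with baselines alpha/beta/gamma/remainder = 0.45/0.20/0.10/0.25
(alpha-dominant resting EEG; the remainder is the 1–8 Hz share), signs
s = (−1, +1, +1, 0), region coupling r_c from 0.4 (prefrontal) to 1.0
(occipital) — mirroring the empirical pattern that frontal channels track
higher cognition rather than the memory task — trial noise ε truncated at
3 sd (default sd 0.3), and `trait` a per-subject, per-channel, per-band
offset (truncated Gaussian, sd 0.5, cut at 2 sd) shared between rest and
task: the stable individual spectral fingerprint that makes grouped
validation necessary. Ratios are the softmax composition of the four
components scaled by 0.95, so they always lie in (0, 0.95), sum to at
most 0.95, and — because softmax is monotone and the softplus drive is
strictly positive — the energy-shift signs are exact for every subject
and channel at zero trial noise, whatever the trait offsets.

Completion times are log-normal, `t = 60·exp(−0.3 θ + ε)` s with label
noise sd 0.2, giving corr(θ, z) ≈ 0.8 at large n. Raw time series are
sums of band-limited Gaussian noise (1–8, 8–13, 13–30, 30–44 Hz built in
the Fourier domain), each component calibrated against the same
Hann-windowed periodogram the feature extractor uses, so extracted ratios
recover their targets within 0.05.

Defaults follow the study profile: 20 subjects × 2 sessions × 3 trials =
120 task records plus one resting record per subject; a second profile
(47 × 2 × 112 = 10,528) exercises cohort arithmetic at scale. Session 1
is the word task, session 2 the picture task; labels standardize within
task type.

What the generator does **not** emulate: 1/f spectral slopes, ocular and
muscle artifacts (beyond what preprocessing tests inject), non-stationary
drift, electrode impedance effects, and any band asymmetry in coupling
strength. Passing tests therefore demonstrate internal consistency and
parameter recovery under the declared generative model, not performance
on recorded EEG.

## Numerical choices and degenerate inputs

Defuzzification on a fixed grid makes fuzzy outputs bit-reproducible.
All stochastic procedures take explicit seeds and are deterministic given
them. Degenerate cases are defined rather than left to chance: an
all-zero recording yields zero ratios with a warning; a constant fuzzy
transform degenerates the regression to the label mean; identical FCM
points collapse centroids with a warning; an empty clustering set falls
back to the baseline SVR; a single training point pins the SVR at its
label. Replicate problem sizes (30 studies for the ordering comparison,
1000 replicates for the null-rejection rate at n = 200) were chosen as
the smallest sizes at which the binomial/median statistics are stable.

## Known limitations

The rule base is fixed, not learned; no ANFIS-style tuning. The
evaluation cannot reproduce the original study's numeric error table —
its data are unavailable — so the comparison asserts the qualitative
ordering of methods on synthetic data instead of printed values. EDF
reading is a thin optional wrapper (via mne) and assumes channel names
resembling 10-10 labels.
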