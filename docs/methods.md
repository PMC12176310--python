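# Methods

`wardfusion` implements a complete, testable pipeline for comparing
multimodal recurrent risk models on ward patients: structured vitals/labs
fused with clinical-note concepts (UMLS CUIs) to predict death or direct
ward-to-ICU transfer within 24 hours of each observation. Because real
hospital EHR extracts are private, the package ships a synthetic-cohort
generator with known ground truth; every downstream claim the test suite
makes is a claim about recovering that ground truth.

## The prediction problem

Each encounter is a sequence of observation timesteps. At timestep *t* the
model sees (i) an imputed, piecewise-linear-encoded structured vector, (ii)
hours since admission, and (iii) a representation of the most recent unique
CUIs pulled forward from notes at or before *t* (window capped at 360 by
default; 60–120 at synthetic scale, sized to cover each cohort's typical
unique-concept accumulation so persistent concepts stay visible). The target is a binary label,
label(*t*) = 1 iff the composite outcome occurs in (*t*, *t* + 24 h]. The
window is half-open by design: an event exactly at *t* does not label its
own observation, and observations at or after the event are excluded.

## Synthetic cohorts

The generator draws, per encounter: demographics (sex, race, ethnicity, age
band — independent of outcome by default, with an optional subgroup shift
for stress tests); a length of stay from a shifted exponential (8-hour
minimum, memoryless beyond it — hard clipping would put point masses on
the stay distribution and make label rates time-dependent even under a
null hazard); a latent severity random walk *s_t*; structured features
on a jittered 4-hourly grid (the first `len(structured_effect_log_odds)`
features are noisy views of *s_t*, the rest pure noise), with
missing-at-random gaps plus occasional never-measured features; and note
events — an admission note at ~15 min plus further notes at a mean 12-hour
interval, each carrying a Zipf-distributed burst of background CUIs and,
independently, each designated signal CUI with probability
`signal_cui_prob`.

The per-timestep event hazard is logistic:

    logit p_t = c + Σ_j β_j · feature_{j,t} + γ · |{signal CUIs noted ≤ t}|

Signal CUIs act as *persistent* risk markers — each contributes γ log-odds
from its first mention onward. This mirrors the chronic high-risk
conditions (chemotherapy, dialysis, transplant) that dominate real
concept-importance tables, and it aligns the generating covariate with what
the models can actually see: the pull-forward window keeps every past
unique CUI, so a transient 24-hour effect would be observable only through
a diluted proxy. An earlier all-or-nothing "any signal CUI present" design
was rejected because the indicator saturates and individual injected
effects become unidentifiable.

The intercept *c* is calibrated by bisection on pre-drawn uniforms so the
realized observation-level label prevalence matches `target_prevalence`
(default 0.05, the low-prevalence regime that motivates AUPRC as the
primary metric). Events truncate the encounter. Identical (config, seed)
yields byte-identical cohorts.

Preset study conditions (module-level constructors, not test fixtures):

* `strong_signal_config` — severity loadings (4, 4, 4) with low noise;
  signal CUIs rare but strong (presence 0.08 per note, γ = 4). Rare-but-
  strong is the regime the IDF weighting of the importance score is
  designed for. Used for the attribution-recovery study.
* `separable_config` — structured-dominant (same loadings, feature and walk
  noise 0.1, γ = 1): the outcome is close to a deterministic function of
  inputs the model observes directly, so a sound trainer should approach
  the generating process's discrimination. Used for discrimination sanity.
  These two regimes are deliberately distinct: on a concept-dominant cohort
  the tokenized model's ceiling (≈0.94 AUROC at this scale, versus an
  oracle ≈0.98 using the true logit) reflects the difficulty of estimating
  per-concept effects from 2,000 encounters, not a defect of training.
* `noise_cui_config` — structured signal only, γ = 0: concepts are pure
  noise, the synthetic analogue of the finding that adding note concepts
  does not meaningfully change discrimination.
* `null_config` — no covariate signal; any model's test AUROC must sit
  near 0.5. Stays are long (mean 120 h) because the 24-hour label window
  has a real admission boundary — observations in the first day cannot be
  labeled by triggers that would have preceded admission — and longer
  stays keep that structure a small share of observations.

What the generator does **not** emulate: realistic physiology or lab units,
note text, inter-site distribution shift beyond a seed change, ICU
readmissions, informative observation timing. Passing tests therefore
demonstrate correctness of the pipeline's mechanics and recoverability of
injected effects, not clinical performance.

## Structured preprocessing

Carry-forward imputation uses only current and past values; lactate/blood-
gas-class features carry at most 24 h before falling back to the
development-cohort median (midpoint convention for even counts). Remaining
gaps take the median. Features are then piecewise-linear encoded: with
boundaries b_0 < … < b_K, component k is clip((x − b_{k−1})/(b_k − b_{k−1}),
0, 1) — monotone componentwise, and for in-range x the weighted sum of
components reconstructs x exactly. Boundaries are per-feature quantiles of
development-cohort values (default 16 bins; 8 at synthetic scale), with
duplicate quantiles collapsed. Imputation precedes encoding. Development-fit
medians and boundaries are serialized to a JSON sidecar and reused
bit-exactly on validation cohorts.

## Concept parameterizations

The vocabulary is built on the development cohort only: CUIs in at least 5
distinct admissions, tokens assigned by descending admission document
frequency (ties by CUI string), 0 reserved for padding and 1 for
out-of-vocabulary. External cohorts are harmonized by intersection with the
development vocabulary. Five parameterizations feed the models:

* **ST** — tokens into a learned embedding table (init scale 0.01, padding
  row pinned to zero).
* **ICDR-T** — CUIs sharing a 3-character ICD-code prefix collapse to one
  rollup token; code-less CUIs share group 0; codes shorter than 3
  characters key on their full string. Rollup built on development data,
  applied frozen.
* **ICDR-BV** — the rollup groups as a presence/absence binary vector.
* **SE** — tokens index a frozen pretrained embedding matrix (synthetic
  provider by default; any per-CUI vector source plugs in).
* **CC** — embeddings PCA-reduced (centered, deterministic sign convention;
  768 → 100 by default, bounded by n − 1), pairwise cosine distances
  (zero-norm vectors handled explicitly), average-linkage agglomerative
  clustering cut at a distance threshold; clusters as a binary vector. A
  helper finds the exact cut height for a target cluster count from the
  dendrogram merge heights. Cluster indices are relabeled by smallest
  member token for determinism.

Window alignment keeps, per timestep, each CUI's latest occurrence at or
before the timestep, ranked most-recent-first, truncated, padded. Ties
(note timestamp equal to the structured timestamp) are included.

## Models

All six variants share an intermediate-fusion skeleton: structured vector →
dense + dropout; hours → Time2Vec (component 1 linear, the rest
sinusoidal); concatenated → GRU/LSTM stack emitting one hidden state per
timestep. The concept branch (embedding + dropout + window pooling + dropout
→ recurrent stack, or binary vector + dropout → recurrent stack) runs in
parallel; the per-timestep representations concatenate into a single dense
unit with sigmoid — one risk score per observation. Average pooling divides
by the fixed window length with padding slots zero-masked, so the pooled
vector stays proportional to the *sum* of present-concept embeddings and
additive concept effects remain linearly representable; max pooling
operates on the masked embeddings (saturating at ≥ 0).

The networks and their gradients run on a small reverse-mode automatic
differentiation engine written for this package (`wardfusion.nn`): a
tape-based Tensor over numpy arrays with the operations the architecture
needs, verified against finite differences. Gradients flow to inputs as
well as parameters, which is what integrated gradients requires.

Training: per-timestep binary cross-entropy masked over padding, Adam
(default learning rate 10⁻², batch 32, 16 for SE), early stopping when no
epoch among the last 5 improved the best validation AUROC by ≥ 0.005;
weights from the best epoch are restored. Splits are disjoint by encounter
(80/20). Hyperparameter search (`tune`) maximizes validation AUROC over a
declared space, by random search or a Gaussian-process surrogate with
expected improvement ('smbo'), 20 trials by default, deterministic given
the seed. Causality holds by construction and is perturbation-tested:
scores at *t* never depend on inputs after *t*.

## Evaluation

AUPRC (average precision; PR interpolation is optimistic and deliberately
avoided) is primary, AUROC (Mann-Whitney, ties count half) secondary; both
are checked against exhaustive brute-force oracles to 10⁻¹². 95% CIs use a
percentile bootstrap: 1000 iterations, each resample drawn with replacement
at observation level with size ⌈0.20 n⌉; single-class resamples are redrawn
and counted. Operating points flag the top 1/5/10/15% of scores; the
threshold is the score at rank ⌈f·n⌉ descending, all tied observations are
flagged, and the realized flag count is reported (so PPV × n_flagged equals
the true-positive count exactly). Brier score is the mean squared
score-label difference. Subgroup tables repeat AUROC/AUPRC + CIs per sex,
race, ethnicity and age band; single-class groups are reported absent.

## Attribution

Integrated gradients along the straight path from a zero-embedding baseline
(the padding representation) to the embedded CUI window, right-endpoint
Riemann approximation with 50 steps by default (12 at desk scale;
completeness error shrinks like 1/m and is self-checked at 512 steps). The
scalar attributed is the masked sum of per-timestep scores; because
encounters and timesteps do not interact through the attributed input, the
batched attribution decouples into each encounter's own, and summation over
embedding dimensions, timesteps and encounters matches summing each score's
own attributions. The global score per CUI multiplies the signed raw sum by
ln(N/df) over a balanced (equal cases/controls) encounter sample — natural
log, with N the realized sample size. The attribution study reports, per
CUI, the median rank over three training seeds: the median is the estimator
of record because run-to-run training stochasticity moves which single
concept is weakest.

## Numerical and procedural choices

* Timestamps are float hours since admission; admission is t = 0.
* Median convention: midpoint for even counts.
* Sigmoid inputs are clipped at ±60 before exponentiation; BCE adds 10⁻¹²
  inside logs.
* Bootstrap CI method: percentile 2.5/97.5.
* Zero-threshold clustering returns singletons; a single point returns one
  cluster; coincident points (zero cosine norm after centering) are
  distance-0 pairs.
* Encounters with no usable timesteps are skipped with a warning, not
  errors.
* Desk-scale problem sizes used by the test suite and acceptance script —
  2,000-encounter strong cohorts, 600–1,500-encounter comparisons, hidden
  16–24, embedding 8–32, window 60 — are the package's chosen balance of
  statistical resolution against a single-CPU workflow; all are config.

## Known limitations

The autodiff engine is minimal by design (no GPU, no fused kernels);
training beyond ~10⁴ encounters is slow. The synthetic vocabulary (300
CUIs, 32-dim embeddings) is far smaller than a real extraction (~31k CUIs,
768-dim); dimensioning defaults for the real scale are accepted as config
but untested at that scale. Attribution defaults to the ST model — the mode
whose embedding input makes the path integral directly interpretable;
other modes are permitted but experimental. Subgroup fairness results on
synthetic cohorts only demonstrate the *mechanics* of subgroup evaluation,
since demographics are generated independently of outcome.
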