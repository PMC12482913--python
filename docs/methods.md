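# Methods

`trajrisk` estimates the probability of clinician-defined critical events
(in-hospital mortality, ICU admission, prolonged stay, composites, ED
outcomes) by simulating a patient's future as a token sequence.  The
pipeline is: tokenize event-level EHR data into patient health timelines
(PHTs), fit an autoregressive next-token model, sample N future timelines
(fPHTs) from a patient's context, and count the trajectories in which each
tracked event occurs.

## Tokenization

A PHT opens with a six-token static block — age tens digit, age units
digit (digits reuse the quantile alphabet, digit *d* → Q(*d*+1), so ages
0–99 need no extra tokens; a 46-year-old starts Q5 Q7), gender, marital
status, race, and BMI class (standard clinical cut points 18.5 / 25 / 30).
Each subsequent clinical event contributes:

* an **interval token** when ≥ 5 minutes elapsed since the previous event.
  The 19 bins form a geometric ladder partitioning [5 min, ∞):
  5 m, 15 m, 45 m, 1.5 h, 3 h, 6 h, 12 h, 1 d, 2 d, 4 d, 1 w, 2 w, 1 mo,
  2 mo, 3 mo, 6 mo, 1 y, 2 y, 5 y.  Sub-5-minute gaps emit nothing, which
  is also why timestamps are truncated to minute resolution.  Each bin
  carries a representative duration (geometric midpoint of its edges; the
  open top bin uses twice its lower edge) that simulated clocks sum.
* **code tokens**: ICD-10-PCS procedures decompose positionally into 7
  single-character tokens; ICD-10-CM diagnoses into a 3-character category
  token plus one token per extension character (1–5); ATC drug codes into
  one cumulative-prefix token per hierarchy level (1–5); labs, vitals and
  special events (admission, discharge, ICU admission, death, ED
  registration/discharge) are single tokens.  No event exceeds 7 tokens.
* a **quantile token** Q1..Q10 for numeric values, binned by per-code
  decile edges fitted on the training split (empirical CDF with linear
  interpolation; ≥ 20 observations per code, otherwise pooled scheme-level
  edges).  A value equal to an edge goes to the upper bin; values outside
  the training range clamp to Q1/Q10; a constant training distribution
  maps everything to Q1.

Timelines end with an explicit end-of-timeline token so a trained model
learns to terminate.  Subjects with no tokenizable events are excluded and
counted.

## Monte-Carlo risk estimation

Given a context (the PHT up to an anchor such as hospital admission), the
sequence model is sampled at temperature 1 until a stopping condition: a
terminal token (death, discharge, timeline end), the simulated-time
horizon, resolution of every tracked event, or a token cap (default 2048;
capped trajectories are logged as censored and their unresolved events
count negative — an event token observed before the cap stays positive).
With M of N trajectories positive, the estimate is p̂ = M/N with an exact
binomial (Clopper–Pearson) 95% interval, chosen over the normal
approximation because M = 0 and M = N occur routinely at the default
N = 100.  Risk is additionally reported on five ordinal levels at 0.2-wide
probability bands.

Competing risks are handled structurally: all events tracked for one
patient share the same trajectory ensemble, so a sampled death terminates
the course and removes any later ICU admission or prolonged stay from that
trajectory.  Composite endpoints OR the per-trajectory flags — never a
product of marginals — so dependencies are inherited.  Each trajectory
draws from an independent RNG stream derived from (seed, trajectory
index), making estimates reproducible and order-independent.

Prolonged-stay style events are time-threshold targets: a trajectory is
positive once its simulated clock (summed interval-token representatives)
passes the threshold before a terminal token.  Observed labels use wall
clock instead; the two disagree by at most the width of the interval bins
straddling the stay, which is the price of a discrete time alphabet.

## Tasks and dynamic components

Tasks are declarative token-set specifications (positive set, terminal
set, optional horizon, anchor rule), so new clinical endpoints need no
model retraining.  Built-ins: hospital mortality (death before
discharge), ICU admission, prolonged stay (threshold = training-cohort
90th-percentile length of stay), their composite, hospitalization at
triage, critical outcome within 12 h of triage, and ED re-presentation
within 72 h of ED discharge.  A running monitor deactivates the ICU
component once the patient is in the ICU, drops mortality after
death/discharge, and re-targets the prolonged-stay component up a
threshold ladder (10 d → 15 d → 20 d, then +5 d per rung) as the observed
stay overtakes it.

## Sequence models

The Monte-Carlo layer consumes a minimal contract — `next_distribution`,
`sample` — with two implementations:

* a **tabulated order-1 Markov model**, the exact oracle used throughout
  the tests (its absorption probabilities are computable in closed form);
* a **decoder-only transformer** (learned token and position embeddings,
  pre-norm causal multi-head attention, GELU MLP, Adam) implemented in
  NumPy with hand-derived gradients, verified against finite differences.
  The desk-scale default is 4 layers, 4 heads, width 128, context 256;
  the test suite uses width 64 and contexts of 16–48 — chosen to match the
  short synthetic timelines — trained for 600–1000 steps.  Generation uses
  per-layer key/value caching so a sampling step costs one token rather
  than one full context re-encode; trajectories from many patients are
  interleaved into shared batched passes.

## Synthetic cohorts and ground truth

The generator emulates a hospital course as a semi-Markov process:
ED triage → {ward, ED discharge}; ward → {ICU, death, discharge};
ICU → {death, discharge}; absorbing death/discharge/ED-out.  Each state
carries competing exponential hazards per destination, conditioned on a
latent low/high severity (mixture weight 0.3 high).  Defaults: triage
mean residence 4 h with admission probability 0.30 (low) / 0.85 (high);
ward mean residence 3 d / 2 d with ICU shares 0.08 / 0.45 and death
shares 0.01 / 0.12; ICU death shares 0.10 / 0.35.  Because destinations
are hazard ratios, scaling one hazard (e.g. quadrupling death) reshapes
the other outcomes exactly as a cause-specific competing-risks model.

Severity is observable through lab values (normal with means 1.5 vs 5.0,
sd 0.8; three draws at triage, two on the ward), deliberately
well-separated so the tokenized context identifies severity and learned
risk scores can approach the Bayes-optimal discrimination computed from
the generating probabilities.  After an ED discharge, a subject re-presents
with probability 0.10 / 0.25 after an exponential (2 d mean) delay.

Every queried outcome probability is exact: courses are enumerated path by
path (the default chain is acyclic; enumeration truncates below 1e-12
mass and verifies the total), and length-of-stay tails convolve the
per-state exponential residence densities on a 1-hour grid (tolerance
~1e-3).  What the generator does **not** emulate: realistic code
vocabularies (one lab code), ward→ICU→ward loops, co-morbidity structure,
measurement missingness, or calendar effects — so green tests demonstrate
the correctness of the machinery on a known process, not clinical
performance on real EHRs.

## Explainability

Risk trajectories re-run the estimator from successive context prefixes;
position j uses exactly tokens [0, j] and shares the per-trajectory seed
streams, so the final position reproduces the standalone estimate
bit-for-bit.  Token attribution ranks positions by the signed change in
p̂ (computed as exact M/N rationals so equal steps tie exactly; ties break
to the later position) and flags a change significant only when
consecutive Clopper–Pearson intervals are disjoint, keeping the false
highlight rate on a flat process at the noise level.

## Evaluation

AUC uses the Mann–Whitney formulation with ties counted ½ (scikit-learn's
implementation); confidence intervals come from a seeded subject-level
percentile bootstrap (default B = 1000; degenerate one-class resamples are
redrawn and counted); calibration curves compare mean predicted
probability with observed frequency on ten equal-width bins (empty bins
omitted); the Brier score is the mean squared probability error.

## Numerical and design notes

* Quantile tie rule (upper bin at edges) and the degenerate-distribution
  rule (everything → Q1) are fixed conventions; both are documented above
  and tested.
* One interval token per gap; the top bin is open-ended rather than
  composing long gaps from multiple tokens — the simplest rule consistent
  with a 19-symbol time alphabet.
* The transformer is float32 throughout; training is fully seeded and the
  loss history is reproducible on a fixed platform.  Batched, KV-cached
  generation is numerically equivalent to full recompute to ~1e-4 in the
  next-token probabilities (causal masking makes right-padding inert) and
  exactly reproducible for a fixed seed and code path.
* Censored trajectories (token cap) count unresolved events negative,
  biasing estimates conservatively downward; the censor count is reported
  on every estimate.
* Known limitations: simulated clocks are representative-duration sums,
  so prolonged-stay estimates inherit interval-bin quantization; the
  synthetic prolonged-stay endpoint is only weakly severity-linked, so its
  standalone discrimination is near chance even for the exact model —
  mortality, ICU and the composite carry the discrimination signal.
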