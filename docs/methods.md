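# Methods

## The model

`gazeforage` simulates where and when a human observer looks while
free-viewing a dynamic conversational scene. The scene is abstracted into a
*landscape* of audio-visual patches — 2-D Gaussians `(μ_p, Σ_p)` with a
social value `V_p` attached to the patch class (speaking face, listener
face, gesture, center bias). Gaze behaves like a forager on this landscape:
it exploits the current patch locally, decides when to give it up and which
patch to visit next, and relocates.

### Patch choice and giving-up: a race of accumulators

Each visible patch `p` owns an independent drift-diffusion accumulator

    dq_p = I_p(t) dt + c dW_p,       q_p(0) = 0,

integrated by Euler steps `q_p ← q_p + I_p δt + c √δt z`. The first
accumulator to reach the threshold `a` ends the race; its patch becomes the
next gaze attractor. If the winner is the current patch, exploitation
continues and the race restarts from zero; otherwise gaze relocates. The
drift combines two factors, `I_p = Ψ(p, p*) ν_p`:

* the gazing function `Ψ = exp(−φ V_p t)` for the currently exploited patch
  (1 for all others), where `t` is the time since the patch was entered —
  it decays the current patch's own evidence inflow so the process cannot
  stay captured forever; the clock resets only on patch switches, not
  between races on the same patch;
* the relative value `ν_p = η (V_p / V_p*) exp(−κ d)`, where `d` is the
  distance between patch centers expressed in frame diagonals — value
  relative to the current patch, discounted by visibility.

Because every competitor's drift carries the factor `1/V_p*`, valuable
current patches depress the whole field of competitors and are therefore
given up later — the mechanistic analogue of the marginal-value account of
patch residence. Defaults `φ=0.18, η=5, κ=15, a=1.7, c=1` are the values
obtained by grid search against human scanpaths on conversational video;
`δt = 1/60 s` matches the eye-tracker sampling rate.

Numerical notes: the race has no reflecting floor (negative excursions are
allowed, as in the printed SDE); at the threshold, the largest `q` wins and
exact ties go to the lowest patch id; patches that disappear mid-race are
dropped and newcomers join with `q = 0`; a configurable guard (default
30 s) raises on races that never decide, which signals degenerate
parameters rather than a recoverable state.

### Spatial dynamics: one O-U process at two scales

Gaze coordinates follow a mean-reverting Ornstein-Uhlenbeck process
`dr = B(μ_p* − r) dt + σ dW` toward the current attractor, with parameters
switched by the regime flag `s_t`:

* exploitation (`s_t = 0`): per-axis attraction `b = k_b_local / width`
  (width = √ of the covariance diagonal) and `σ = 1` — small wander around
  the patch center;
* relocation (`s_t = 1`): `b = k_b_global / d_rem` with the remaining
  distance `d_rem` to the target expressed in frame diagonals, clamped to
  `[b_min, b_max]`, and `σ = k_sigma_global ×` the mean pairwise distance
  between patch centers — a fast, large-amplitude sweep. Expressing
  `d_rem` in diagonals makes relocation speed independent of pixel
  resolution; with the defaults the clamp `b_max` is active during most of
  a flight, so relocations complete within a few 60 Hz samples,
  saccade-like. A raw-pixel mode (`diag=None`) and a directly proportional
  drift (`relocate_drift="direct"`) are kept for comparison.

Steps use the exact O-U transition,

    x' = x e^{−bδt} + μ (1 − e^{−bδt}) + (σ/√(2b)) √(1 − e^{−2bδt}) z,

which is distributionally exact for any step size; the alternative literal
amplitude `σ·b·(1 − e^{−2bδt})` is preserved behind `ou_noise="literal"`
for comparison, but the exact conditional standard deviation is the
default (the √ is taken to be the intended reading). Relocation terminates
when gaze is within 1 Mahalanobis unit of the target Gaussian (inclusive);
the race is paused while in flight (`race_during_flight=True` enables the
ablation where it is not). Output coordinates are clamped to the frame;
the internal state is left unclamped to preserve the Markov property.

Proportionality constants (`k_b_local=40`, `k_b_global=20`,
`k_sigma_global=0.25`, `b_min=0.5`, `b_max=50`) are package defaults — the
model only requires proportionality — and all live in the `spatial` config
block.

### The simulator

A clip simulation starts at the frame center, targets the nearest patch
(normally the center-bias patch), and then alternates race → relocate →
exploit on a shared 60 Hz clock. The master seed is split into independent
decision and spatial streams, so the spatial path can be replayed in
isolation (a regression test does exactly this). The simulator's inner
loop carries the race as plain arrays and caches the O-U step constants
while the regime, frame and attractor are unchanged; tests pin this hot
path to the module-level operations it mirrors.

## Synthetic scenes

The generator emulates a ~20 s conversational clip at 1280×720, 30 fps:
2–5 faces clustered around the frame center at ~230 px spacing (medium
close-up conversational framing), exactly one of them speaking at any
moment, speaker turns of mean 5 s (shifted-exponential lengths with a 1 s
floor, consecutive turns always switch speaker), an optional gesture patch
~120 px below the current speaker for the duration of a turn, and one
broad center-bias patch fixed at the frame center. Face centers drift by a
bounded random walk (≤2 px/frame per axis); covariances are fixed per face
and mildly anisotropic. Default patch values are
`{speaker: 0.5, face: 0.2, gesture: 0.15, center_bias: 0.15}`.

The clustered framing matters: with `κ = 15` and diagonal-normalized
distances, the visibility factor `exp(−κ d/diag)` only lets patches
interact when their centers are within roughly a fifth of the frame
diagonal — which is what close-up conversational footage looks like, and
what the drift parameterization presupposes. Spreading the same faces
across the full frame width would effectively freeze the race on its
current patch.

What the generator does **not** emulate: measurement noise and blinks,
appearance-driven salience, audio, camera cuts, within-patch structure
(eyes vs. mouth), and speaker-turn correlations with gesture semantics.
Tests passing on these scenes therefore validate the model's internal
consistency and its qualitative behavior (value-dependent residence,
skewed duration distributions, discrimination from a random baseline) —
not performance on real eye-tracking data.

## Event classification

Model trajectories are parsed into fixations and saccades functionally: a
fixation is a stretch during which a static or slowly moving patch is
gazed at, so pursuit-like drift stays inside fixations. The packaged
classifier is a velocity-threshold (I-VT) segmentation: inter-sample
speeds below 5 % of the frame diagonal per second are fixation intervals;
candidate fixations shorter than 50 ms are absorbed into the surrounding
saccade; fixation position is the centroid of its samples. For simulated
trajectories an oracle labeler derives events directly from the regime
labels, giving a classifier-independent path for metric tests; the I-VT
fixation counts track the oracle within ±20 % on synthetic clips.

## Evaluation metrics

*ScanMatch*: fixations are binned on a 14×8 spatial grid and repeated once
per 50 ms of duration (round-half-away-from-zero, minimum one symbol); two
symbol sequences are aligned by Needleman-Wunsch maximizing the total
substitution score, with substitution `max_bin_distance − d(bin centers)`
and gap penalty 0 (both configurable; the bin counts and the temporal bin are the
protocol-fixed settings). Scores are normalized by
`max_substitution × len(longer)`, so identical sequences score exactly 1
and the score is symmetric.

*MultiMatch*: scanpaths become saccade-vector sequences, aligned by
dynamic programming minimizing summed vector-difference magnitude (no
direction/length/duration simplification). Per aligned pair, five
dissimilarities are averaged and inverted into similarities: shape
`|u−v|/(2·diag)`, length `||u|−|v||/diag`, direction (angle difference)/π,
position (source-fixation distance)/diag, and duration
`|d_u−d_v|/max(d_u, d_v)` on the source fixation durations.

The evaluation protocol scores Real-vs-Real (all unordered pairs of
reference observers) and Real-vs-Model (all cross pairs) per clip. When
the model cohort is literally the real cohort, cross pairs include
self-pairs, so the Real-vs-Model mean can only meet or exceed the
Real-vs-Real mean — equality holds after excluding self-pairs.

## Statistical machinery

Per-clip score matrices (clips × models) go through distribution gates —
Shapiro-Wilk per column with Bonferroni correction, then Bartlett (all
normal) or Levene — that route to ANOVA only if both normality and
homoscedasticity hold, else to the Friedman rank test (tie-corrected,
χ² with k−1 df; an all-tie matrix is defined as statistic 0, p = 1).
Nemenyi critical differences use `CD = q_α(k)·√(k(k+1)/(6N))` with
`q_α(k)` from the studentized-range table (k ≤ 10, α ∈ {0.05, 0.10}),
embedded statically and cross-checked against `scipy`'s studentized-range
distribution. Effect sizes are Cohen's d with pooled SD and the
conventional negligible/small/medium/large cuts at 0.2/0.5/0.8 — a
convention of this package, not a claim about any external analysis.
Score densities are Gaussian KDEs with Scott's bandwidth.

## Validation design and problem sizes

The package validates itself against independent oracles rather than
external data:

* race first passage — closed forms (winner `argmax I`, hitting time
  `a/I`) for the noise-free race, and inverse-Gaussian moments
  (mean `a/I`, variance `a c²/I³`) for the stochastic single racer. The
  stochastic check integrates 10⁴ racers with the package's step primitive
  at `δt = 5·10⁻⁵ s`; at the default 1/60 s step the discrete-monitoring
  overshoot (~`0.58·c·√δt/I`) exceeds the Monte-Carlo tolerance, so a fine
  step isolates the law itself from monitoring bias.
* O-U transition — two-sample KS (α = 0.01, 10⁴ draws) against a
  1000×-finer Euler-Maruyama chain over a 3×3 grid of `(b, σ)`, plus
  stationary-variance checks against `σ²/(2b)`.
* value-residence monotonicity — mean exploitation-episode duration over
  200 episodes per value level `V ∈ {0.1, 0.3, 0.5}` on a two-patch
  landscape with a speaker-valued competitor at conversational (150 px)
  spacing, where the value-ratio mechanism dominates the opposing
  gazing-decay effect.
* metrics — identity scores on identical inputs, worked fixtures for the
  0.5 duration and 0.5 direction scores, and exhaustive enumeration of all
  global alignments on seeded samples of short four-symbol sequences.
* statistics — Friedman vs. brute-force comparison-counting ranks on every
  3×3 matrix over {1,2,3} and a 20 000-matrix seeded sample of the 3×4
  space; CD monotonicity in N and k.
* end-to-end discrimination — 50 meta-replicates, each with six
  independent 20 s synthetic clips as repeated-measure blocks and cohorts
  of 10 reference and 10 same-parameter model observers per clip: the
  Friedman test over clip blocks comparing Real-vs-Real with Real-vs-Model
  ScanMatch means should be non-significant in ≥80 % of replicates, while
  the Real-vs-Random mean falls below Real-vs-Real in ≥95 %. Clips are the
  blocking unit because blocks must be independent; blocking by observer
  would share each cohort across all blocks and inflate the Friedman
  rejection rate far above its nominal level.
* distribution shape — pooled fixation durations of a five-observer cohort
  per seeded run are right-skewed (positive sample skewness) in ≥95 of 100
  runs; pooling mirrors how duration distributions are estimated in
  practice, since the skewness of a single ~9-fixation clip is dominated
  by small-sample noise.

`scripts/acceptance.py` recomputes these quantities from scratch at
moderate problem sizes (e.g. 20 discrimination replicates) and writes them
as JSON.

## Known limitations

* Patch values are class priors; no within-clip value dynamics beyond the
  speaker turn flag.
* Saccade direction statistics are not modeled — relocations head straight
  for the target — so direction-sensitive similarity to human data is
  expected to be weak.
* The exploitation noise scale `σ = 1 px/√s` yields very tight
  within-patch wander; fixational scatter in real recordings is dominated
  by measurement noise that the model does not emulate.
* The I-VT classifier is a deliberately simple stand-in for probabilistic
  event segmentation; its single threshold cannot separate slow saccades
  from fast pursuit.
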