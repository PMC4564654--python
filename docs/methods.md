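# Methods

## The model

`tonalnet` trains a fixed-architecture multilayer perceptron
(2232 → 45 → 30 → 24) to name the key of a monophonic tone-chroma sequence.
The input code is positional: 186 blocks of 12 units, block *p* one-hot in
the chroma sounded at serial position *p*, all-zero beyond the melody's
length. Zero padding means absent positions contribute nothing to the first
affine map, so short probes are read out through the same weights as long
training melodies. Hidden and output units use the hyperbolic tangent
sigmoid, evaluated through the numerically stable library `tanh` (identical
to the exponential form to machine precision, without overflow).

Teacher signals keep the {0, 1} one-hot coding even though outputs range
over (−1, 1); the 0 target sits mid-range, which slightly regularizes
non-target units toward indifference. A symmetric {−0.9, +0.9} coding is
available (`TrainingConfig.target_coding="symmetric"`, off by default).
Binarization of outputs (1 if strictly positive, else 0 — an exact 0 maps
to 0) is a readout for interpreting output patterns; it never enters the
gradient, which is taken on the raw outputs under squared error.

Training is plain online stochastic gradient descent: items are shuffled
each epoch from the run's seed, presented once each, and weights updated
per item. There is no momentum, no weight decay, no adaptive schedule —
deliberately, since the scientific claim is about what mere exposure plus
gradient learning yields. The per-item update loop is compiled with numba
and exploits input sparsity (a melody of L tones touches L of the 2,232
first-layer weight columns); `loss_and_gradients` is an independent
pure-numpy backpropagation path used to verify the compiled kernel, and
both are checked against central finite differences.

Initialization is i.i.d. uniform on [−0.1, +0.1] (config-exposed). The
single-run default learning rate is 0.01. Checkpoints (deep parameter
copies) are taken every `checkpoint_interval` epochs — every 5,000 of
50,000 at full scale, giving 10 test times; an epoch-0 untrained baseline
can be prepended with `include_baseline`. Evaluation is strictly read-only.

## The synthetic corpus

The corpus generator emulates the *statistics* of a children's-songbook
training set, not its notes: 315 major-key and 41 minor-key base melodies
(the heavy major-mode skew of Western children's repertoire), lengths
uniform on [17, 186] tones, tone content drawn i.i.d. from a tonic-relative
scale-degree profile. Default profiles weight in-scale degrees by the
Krumhansl–Kessler probe-tone hierarchy (tonic, dominant, mediant heaviest)
and reserve 2% total mass for out-of-scale degrees; a per-melody cap
(`out_of_scale_rate`, default 5%) resamples excess out-of-scale draws, so
melodies are overwhelmingly diatonic but not sterile. Minor-mode scale
membership is natural minor plus the raised leading tone. Profiles are
plain 12-vectors in the config, so published tone distributions can be
substituted directly.

Two structural choices matter:

- **Tonic-triad anchoring.** Each melody opens and closes on a tonic-triad
  degree (0, 4, 7 major; 0, 3, 7 minor), sampled with the profile's
  relative weights so the tonic itself is likeliest. Anchoring on stable
  chord tones operationalizes "one clear key per melody". Anchoring on the
  tonic *alone* was tried first and rejected: it makes the opening tone a
  deterministic cue to the key, the network learns little else, and probe
  identification degenerates into first-tone lookup. Real melodies open on
  chord tones, not invariably on the tonic.
- **Transposition closure.** Every base melody appears in all 12 same-mode
  transpositions (4,272 items per epoch at full scale). Degrees are sampled
  tonic-relative, so after closure the tonic-aligned degree distribution is
  *exactly* equal across keys of a mode — no key is easier than another,
  which the tests assert as an exact invariant.

What the generator does **not** emulate: melodic contour and stepwise
motion (tones are i.i.d., real melodies move by small intervals), rhythm
and meter (isochrony is assumed), phrase structure, motivic repetition, and
any sequential harmony within training melodies. Passing tests therefore
show that *distributional* exposure suffices for the scale-before-harmony
trajectory in this architecture; they do not show how sequential structure
in real corpora would change its speed or asymptote. This is also why the
harmony contrast below is carried by triad *grouping* in the probes rather
than by learned progressions.

## Test conditions

The three five-sequence probe sets are deterministic nine-tone fixtures
(three 3-tone groups, lengths matched across conditions to remove a length
confound), all nominally C major:

- **in-scale/regular-harmony**: each 3-tone group is a C-major triad
  outline in I–V–I or I–IV–I order; four sequences open on the tonic root,
  one on the mediant.
- **in-scale/irregular-harmony**: C-major scale tones with no 3-tone window
  forming any major or minor triad. Opening tones mirror the regular set's
  (four tonic, one mediant) and most sequences close on the tonic, so the
  regular/irregular contrast isolates the implied-harmony property (triad
  grouping) rather than opening-tone typicality — with tonic-anchored
  training melodies, an uncontrolled opening tone would dominate the
  contrast.
- **out-of-scale/irregular-harmony**: chromatic sequences containing tones
  outside the C-major set.

`generate_condition_sequence` samples additional condition-conforming
sequences for robustness work. Readout is argmax over the 24 raw outputs;
exact ties (measure-zero in practice) break to the lowest unit index with a
logged warning. Normalized correct-key activation maps the C-major output
linearly from (−1, 1) to (0, 1) and averages over the five sequences.

## The multi-run study and statistics

`run_experiment` trains `n_runs` networks (seeds `base_seed + i`) on a
shared corpus realization (per-run regeneration is a config flag),
evaluates every checkpoint, and excludes runs whose final training
agreement falls below `max(2 × chance, exclusion_threshold)` — chance is
1/24, the default threshold 10% — logging every exclusion. Gradient
descent from random initialization can occasionally stall in a poor
minimum; the floor makes that call explicit and reproducible.

Trajectories over retained runs (runs as subjects) are analyzed with a
classical two-way repeated-measures ANOVA: each effect (condition, epoch,
interaction) is tested against its own subject-interaction stratum with
uncorrected degrees of freedom (a Greenhouse–Geisser epsilon is attached
for reference). Simple main effects of condition at each epoch use the
**pooled-error convention**: the condition-by-subject and
condition-by-epoch-by-subject strata are pooled, giving an error df of
(a−1)(S−1) + (a−1)(b−1)(S−1) — with 9 subjects, 3 conditions and 10
epochs, F(2, 160). Pairwise contrasts per epoch are t tests of the
condition-mean difference against that same pooled error term, flagged at
a Bonferroni-adjusted alpha (default familywise 0.05) — with handfuls of
runs, per-epoch paired t tests would have almost no power and their error
estimate would be inconsistent with the simple-main-effect convention. A
degenerate zero error term makes any nonzero difference significant. The
decomposition is hand-implemented (the pooled convention needs the raw SS
strata) and is verified in tests against a brute-force oracle, a worked
example computed by hand, pingouin's omnibus table, and a 1,000-rep null
simulation of the type-I error rate.

## The reduced-scale study

The package's standard study (`small_study_config`) scales the full design
(356 base melodies × 12, 50,000 epochs, 10 runs — config-reachable but
hours-long) down to a few CPU-minutes: 120 base melodies (106 major + 14
minor, preserving the 315:41 ratio), 1,440 training items, 5 runs of 3,000
epochs, checkpoints every 300. Two scaling choices:

- **120 base melodies** rather than fewer: nine-tone probes read only the
  first nine position blocks, and with very small corpora the per-position
  chroma statistics (≈ one sample per base melody per key) are noisy enough
  to dominate probe readout.
- **learning rate 1e-4** rather than the 0.01 single-run default: with far
  fewer items and epochs than the full design, larger rates converge before
  the first checkpoint and leave no trajectory to measure. The reduced rate
  places the learning dynamics across the 10 checkpoints, matching the
  regime of the full-scale design, where performance is still rising
  mid-training.

With these conditions the seeded study shows the package's headline
pattern: out-of-scale identification pinned at 0% at every checkpoint,
in-scale conditions separating from the out-of-scale condition from the
first checkpoints, the regular-harmony advantage over irregular harmony
strengthening with training, and training agreement near ceiling.

## Numerical and degenerate-input choices

- tanh via the stable library form; literal exponentials would overflow.
- Squared-error loss on raw outputs; binarization excluded from gradients.
- Argmax ties break to the lowest index, logged.
- Non-finite epoch loss raises a divergence error naming the epoch.
- Empty corpora, unaugmented training corpora, melodies over 186 tones,
  constant profiles in correlations, and unbalanced ANOVA designs raise
  typed errors rather than propagating NaNs.
- Checkpoint intervals that do not divide `n_epochs` force a final
  checkpoint at `n_epochs`.
- All randomness flows from explicit integer seeds (numpy `default_rng`);
  repeated runs are bit-identical.

## Known limitations

- In the reduced-scale study both sensitivities are measurable from the
  first checkpoint: scale sensitivity never lags harmony sensitivity (the
  ordering the model is meant to show), but the *significance* ordering —
  the in-scale/out-of-scale contrasts reaching significance at an earlier
  checkpoint than the regular/irregular contrast — is not reproduced. With
  an i.i.d. profile corpus the harmony cue is itself distributional, so the
  regular-harmony advantage is large as soon as any key knowledge exists,
  while five runs give little power to detect the small early
  irregular-harmony advantage over the out-of-scale floor.

- The i.i.d. corpus generator omits sequential structure; the network can
  therefore learn positional-distribution cues but not progressions, and
  the probe-set irregular-harmony level is sensitive to fixture design in
  a way the full songbook corpus presumably was not.
- Nine-tone probes exercise only positions 0–8 of a 186-position input;
  conclusions about long-melody readout rest on the training-agreement
  measure, not the probes.
- The minor mode is both rare in the corpus (41/356) and structurally
  harder (shared pitch sets with relative majors); minor-key behavior is
  not separately validated.
- Run counts of 5–10 give the repeated-measures tests limited power; the
  pairwise significance patterns stabilize only once condition separations
  are large.
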