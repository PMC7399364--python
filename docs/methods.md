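# Methods

## The feature-learnability metric

Feature-learnability asks: how much information about a somatosensory
stimulus does a given neural-signal feature carry, as seen by a fixed,
standardized decoder? Given labeled trials (4 stimulus types × 4 limbs =
16 classes), a feature set is scored by training one standardized
classifier on the per-electrode feature values and reading off the mean
of the diagonal of its row-normalized test confusion matrix, expressed in
percent. Because the classifier is held fixed across every comparison, a
difference in learnability is attributable to the inputs, not the model.

Two evaluation protocols:

* **WIA (within individual animal).** For each animal, the rows are split
  70/15/15 into train/validation/test, the network is trained, and the
  test confusion recorded; this is repeated `n_repeats` times (default
  10) under fresh seeded splits and initializations, and the repeat
  confusions are averaged into one representative matrix per animal.
  Representative matrices are averaged across animals into the grand
  matrix; learnability = 100 × mean(grand diagonal), with the SEM taken
  across the per-animal diagonal means (sample SD / √n_animals; reported
  as 0 with a warning when n = 1).
* **LOO (leave-one-animal-out).** Each fold trains on the pooled rows of
  all other animals (70/30 train/validation, no test fraction) and tests
  on every row of the held-out animal. The WIA–LOO gap measures how much
  of the decodable structure is animal-specific.

Chance level is 100/K (6.25% for all 16 classes; 12.5% when the decoder
is restricted to the 8 tactile-dominated or 8 proprioception-dominated
classes, which restricts both the input rows and the output layer).

## The standardized classifier

A single-hidden-layer pattern network: 42 tanh hidden units, softmax
output over the classes present, cross-entropy loss, full-batch gradient
descent with momentum 0.9 and a multiplicative adaptive learning rate
(initial 0.01; ×1.05 after an improving epoch; on an overshoot of more
than 4% the step is discarded and the rate ×0.7). Early stopping keeps
the best-validation weights and stops after 6 consecutive epochs without
validation improvement (max 1000 epochs). Inputs are min–max mapped to
[−1, 1] per column; zero-variance columns map to 0 with a warning rather
than erroring, so degenerate windows (e.g. silent pre-stimulus spans)
still evaluate. Targets are kept one-hot: a {0,1}→{−1,1} affine remap of
one-hot targets, as some toolboxes apply by default, is a no-op for a
softmax/cross-entropy output up to the inverse remap, so nothing is
gained by carrying it. Argmax prediction breaks ties toward the lowest
class index. The hidden size of 42 was selected by scoring candidate
sizes between 16 (the output count) and 154 (the largest input count) on
the average of the smallest (7-input) and largest (154-input) problems;
`select_hidden_size` reproduces that procedure.

Training is deliberately plain, fully deterministic under (table, spec,
seed), and is treated as a measuring instrument: its hyperparameters are
never tuned per feature set.

## The 22-feature battery

Per electrode and analysis window (start relative to stimulus onset):

| category | features |
|---|---|
| HF (4) | spike amplitude (mean prominence, μV), spike count, integral of rectified HF trace (μV·s), mean spike width at half prominence (ms) |
| LF (5) | sum / max / mean burst prominence (μV), burst count, mean burst width (ms) |
| HF PSD (8) | peak spectral density in 200–600, 600–1000, 1000–1500, 1500–2000, 2000–2500, 2500–3000, 3000–3500, 3500–4000 Hz |
| LF PSD (5) | peak spectral density in 4–8, 8–13, 13–40, 40–80, 80–200 Hz |

Signal conditioning is zero-phase (forward–backward `sosfiltfilt`, odd
reflection padding) Butterworth filtering: 550–3300 Hz order 5 for the
spiking band; the LF envelope is the full-wave-rectified HF trace
low-passed at 80 Hz (order 5); spectral features come from a 4–5000 Hz
order-8 conditioning filter. Filters are applied once to the whole trial
and features are then windowed, so window edges carry no filter
transients. At the 10 kHz desk rate the broadband upper corner sits at
Nyquist and only the 4 Hz high-pass edge is applied — the spectral
ceiling of the battery is 4 kHz either way.

The LF feature list mirrors the HF list's width statistic
(`lf_mean_burst_width`) as its fifth member; burst amplitude statistics
alone leave a natural gap that the width fills symmetrically.

**Peak PSD.** Each band's value is the maximum of a Hann-tapered,
zero-padded periodogram of the windowed segment (NFFT = next power of two
≥ fs, so the frequency grid is ≤ 1 Hz). A 60 ms window cannot natively
resolve the 4–8 Hz band; zero-padding provides a deterministic, documented
interpolation of the spectrum so every band always contains bins. The
value is an interpolated peak density, not a claim of sub-window-length
frequency resolution.

**Event detection.** Spikes and bursts are local maxima whose height
*and* topographic prominence exceed a threshold; prominence (height above
the higher flanking minimum, measured within a locality window `wlen`)
is the amplitude measure. The default threshold is 4.5 × the robust
baseline SD (MAD/0.6745 of the pre-stimulus span when ≥100 ms of it
exists, otherwise the trailing rest period), with an absolute floor of
0.5 μV for silent baselines. Two deliberate choices here:

* *Height and prominence, at 4.5σ.* For band-limited Gaussian noise the
  prominences of local maxima concentrate near 4σ (peak-to-trough), so a
  prominence-only cut at ~3.5σ passes hundreds of noise peaks per second;
  requiring height above threshold restores the usual amplitude-threshold
  semantics, and 4.5σ puts the false-event rate near 0.05/s while genuine
  ~30 μV events sit around 9σ. Both the multiplier and `wlen` (2 ms for
  spikes, 500 ms for bursts — it must exceed the event's own base width)
  are configurable.
* *Zero-event convention.* Amplitude and width features are 0 when no
  events are detected, keeping feature tables dense.

Feature tables are tidy DataFrames, one row per trial, columns
`e{1..7}_<feature>` (electrodes outer, features inner; this ordering is
frozen), plus `animal, trial, condition, window_start_ms, window_len_ms`.
Full battery × 7 electrodes = 154 columns; a single feature gives 7.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis relies on,
not the biophysics. Per trial: stimulus-on 2.4 s, rest 2.4 s (tactile:
4.8 s total), plus a 2.4 s return phase for proprioceptive trials (7.2 s);
10 sets of 10 trials per condition (100 per condition, 1600 per animal).
Trials can be synthesized with extra pre-onset signal and a minimum
post-onset span for pre-stimulus baselines and long rolling windows; the
canonical durations hold at the defaults.

Condition-dependent firing-rate profiles (events/s on a unit-gain
electrode), each normalized so its integral over the first second equals
the condition's `target_spike_count`:

* *dowel* — sharp difference-of-exponentials bursts at stimulus onset and
  offset (rise 2 ms, decay 20 ms, peak ≈ 5 ms after the transient), the
  offset burst scaled 0.8, plus a small sustained (slowly-adapting)
  component during the hold phase;
* *brush* — the same structure with slower kernels (rise 12 ms, decay
  45 ms, peak ≈ 22 ms), and with probability 0.3 a second onset burst
  60 ms after the first;
* *flexion / extension* — a raised-cosine bump over the on-phase peaking
  at the movement midpoint (1.2 s), plus a 0.6-scaled bump over the
  return phase; flexion and extension share the shape and differ by
  their target counts (129.1 vs 87.9 events/s-window), so their expected
  count ratio is exactly the target ratio.

Default per-condition statistics: counts 41.6 / 40.0 / 129.1 / 87.9
events in the first second, and mean spike amplitudes 30.2 / 29.7 /
32.4 / 31.1 μV for dowel / brush / flexion / extension respectively.

**Spiking process.** Events are drawn per 0.5 ms bin as Bernoulli with
p = rate × dt (cap 0.95), jittered ±0.05 ms around the bin center. This
is a censored inhomogeneous point process whose expected count equals the
target *exactly* while guaranteeing any two events are ≥ 0.4 ms apart and
therefore always resolve as distinct detected peaks — a raw Poisson
process loses 4–10% of events to peak merging inside dense bursts, which
would silently break count conservation.

**Spike template.** A ~1 ms negative-leading biphasic Gabor wavelet
(Gaussian-windowed 1.4 kHz sine, negative lobes scaled 0.45). Its energy
is concentrated inside the 550–3300 Hz band, so the HF band-pass
preserves the shape; a square-edged biphasic pulse rings under that
filter and creates secondary false peaks. Injected amplitudes are
calibrated so that the configured amplitude equals the *post-filter*
prominence of an isolated spike — amplitude parameters are defined in
the detector's units. Per-spike amplitudes get multiplicative log-normal
jitter (CV 0.15, mean exactly 1).

**Electrodes and laterality.** Each spike is mixed across the seven
electrodes (e1,e2 left | e3,e4,e5 midline | e6,e7 right) by a
limb-dependent gain row: forelimbs — ipsilateral side 1.0, midline 0.8,
contralateral 0.2; hindlimbs — midline 1.0, ipsilateral side 0.4,
contralateral 0.2. This encodes ipsilateral + midline dominance and keeps
left/right hindlimbs distinguishable while making them harder than
forelimbs, as in the recordings the analysis emulates.

**Noise and cohort structure.** Additive white Gaussian noise (3 μV SD)
per electrode plus a slow (<40 Hz) component (2 μV SD). Each animal gets
multiplicative log-normal random effects (SD 0.1) on rates, amplitudes
and per-electrode gains; per-trial substreams are counter-based from
(master seed, animal, trial index), so any trial subset regenerates
bit-identically. An optional `residual_rate_hz` knob adds stimulus-locked
baseline activity outside the stimulus phases; it defaults to 0 because
no principled magnitude is derivable for the rest-period activity real
recordings show, so by default pre-stimulus decoding is at chance.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: genuine local field potentials (the LF
and LF-PSD features see only the spiking envelope and noise, so their
learnability is structurally lower than in real data), mains interference
and amplifier coloration, cross-electrode correlated noise, non-Poisson
spike-train history (bursting, refractoriness beyond the 0.4 ms floor),
electrode impedance drift, and true anatomical variability across
animals. Tests against this generator validate the *pipeline* — that the
measurement chain recovers known injected structure — not the paper's
biological effect sizes.

**Detected-amplitude bias.** Topographic prominence in a dense, noisy
multiunit trace is positively biased: flanking minima fall into noise
troughs and neighbouring spikes' negative lobes. At the default SNR this
inflates mean detected amplitude by ~4–12%, graded with event density
(densest conditions highest). Counts are unaffected. All configured
orderings and responses to amplitude manipulations are preserved, and
the bias is a property of the estimator (as it would be on real data),
so quantification contracts are stated on counts, orderings and ratios
rather than absolute amplitude means.

## Experiments

* **Benchmark selection (adapted SFFS).** Features are first ranked by
  single-feature WIA learnability (mean desc, SEM asc, then declared
  battery order). Each selection round adds the next-ranked unused
  feature from *each* of the four categories (fewer once a category is
  exhausted), evaluates, then repeatedly removes whichever single feature
  most improves the mean until no removal helps. Removed features are
  treated as consumed. The benchmark is the best evaluated set; ties
  favor the smaller set. Evaluations are memoized by feature subset.
* **Window sweep and optimal window.** Learnability is evaluated for
  onset-aligned windows of 20–150 ms in 10 ms steps plus 250, 500 and
  1000 ms (17 lengths). Each feature's curve gets a single changepoint —
  the split minimizing total squared deviation from the two segment
  means, found by exhaustive search over split points (the curve has at
  most 17 points, so brute force is exact and dependency-free); constant
  curves carry no changepoint and are excluded with a warning. Changepoint
  locations are averaged across curves and rounded to the nearest tested
  length (ties toward the shorter window).
* **Rolling decoding.** A fixed-length window (default 60 ms) advances
  every 10 ms from 200 ms before onset to 4000 ms after (421 windows; the
  extra sample at −1000 ms is outside that count and off the 10 ms grid,
  so it is kept as an optional prepended sample). The curve abscissa is
  the window center. Trials must be synthesized with enough pre-onset and
  post-onset span; pooling 4.8 s tactile with 7.2 s proprioceptive trials
  in one sweep therefore uses tactile trials extended with rest-period
  signal at synthesis time (the stimulus is over; the padding is the same
  silent-rest process as the trailing rest phase).

Because filtering is window-independent, sweeps should prefilter each
trial once (`features.prefilter_dataset`) and extract repeatedly; results
are identical to direct extraction.

## Statistics

Feature quantification takes each feature from anatomically relevant
electrodes only — left forelimb from e1–e2, right forelimb from e6–e7,
hindlimbs from the midline e3–e5 — averages within (animal, limb,
electrode, stimulus type) units, and reports per-type means ± SEM across
units, paired t-tests within stimulus category (dowel vs brush, flexion
vs extension, paired by unit) and a two-sample t-test between the tactile
and proprioceptive categories. No mixed-effects modeling or multiplicity
adjustment is attempted; the package reports descriptive means ± SEM and
plain t-tests only.

## Problem sizes and determinism

The test suite and the acceptance script run the pipeline at desk scale:
10 kHz sampling (the 550–3300 Hz band and 4 kHz spectral ceiling survive
under a 5 kHz Nyquist at a quarter of the compute), cohorts of 1–2
synthetic animals with 10–30 trials per condition for learnability
protocols, 5 WIA repeats, and the full 100 trials/condition for
parameter-recovery checks. Sub-seeds always derive from one master seed
via `numpy.random.SeedSequence`; every result in the repository
regenerates bit-identically from (configuration, seed). Memory stays flat
at full scale by streaming trials (`iter_animal_trials`) through feature
extraction instead of materializing whole cohorts.

## Known limitations

* The generator's tactile conditions differ only subtly (counts 41.6 vs
  40.0, amplitudes 30.2 vs 29.7 μV), so dowel/brush confusion dominates
  desk-scale error matrices — faithful to the analysis design, but it
  makes small-cohort learnability values sensitive to trial counts.
* LF PSD features carry little information under the default generator
  (no genuine LFP process), so their learnability hovers near chance on
  synthetic data.
* The WIA protocol's 15% validation split is noisy for very small
  per-animal tables (< ~200 rows), where early stopping can underfit
  relative to LOO's larger pooled validation set; exchangeability
  comparisons between the protocols should use ≥ ~30 trials/condition.
* The `validate` CLI subcommand expects the deposited recordings already
  converted to this package's cohort layout; no reader for the original
  acquisition format is provided.
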