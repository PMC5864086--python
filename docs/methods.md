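# Methods

## Scope

`speechtrack` implements an analysis of how rhythmic brain activity
tracks spoken sentences at the timescales of linguistic units, and of
whether that tracking is perceptually relevant (stronger on correctly
comprehended trials).  The pipeline operates on source-level neural
time series sampled at 150 Hz on a volumetric grid, together with
per-sentence wideband speech envelopes and linguistic annotations.
Sensor-level preprocessing, source localisation (beamforming), forced
alignment and pitch extraction are upstream of this package: it
consumes their outputs (annotations, envelopes or audio, source-grid
series).

## Speech features

**Wideband envelope.**  The waveform is filtered into 8 bands between
100 and 8,000 Hz with third-order zero-phase (forward+reverse)
Butterworth filters, band edges equidistant on the cochlear map; the
envelope is the mean Hilbert magnitude over bands, polyphase-resampled
to 150 Hz.  The cochlear position function is Greenwood's
F(x) = A(10^(ax) − k) with the standard human constants A = 165.4,
a = 2.1, k = 0.88; the literature behind this construction uses equal
cochlear distance without printing a formula, so the map is exposed as
a replaceable function.  When the audio rate is exactly twice the top
edge the highest band is capped marginally below Nyquist so the
band-pass remains realisable.

**Stimulus-specific bands.**  For each category (phrase, word,
syllable, phoneme) the per-sentence event rate is the reciprocal of the
mean inter-onset interval; the analysis band is [min, max] of these
rates across the corpus, rounded to one decimal.  For the reference
corpus this yields 0.6–1.3 (phrase), 1.8–3.0 (word), 2.8–4.8
(syllable) and 8–12.4 Hz (phoneme).  Dividing the syllable band by
three (treating every third syllable as stressed) gives the stress
timescale 0.9–1.6 Hz.  The coefficient of variation of unit lengths is
the population SD of pooled event durations over their mean; population
rather than sample SD is a documented convention, as only "coefficient
of variation" is specified upstream.

**Spectra.**  Welch periodograms are evaluated on a 0.1-Hz grid
(0.1–12 Hz) by fixing the FFT length to rate/0.1 samples and letting
segments be at most half the signal, so at least two overlapping
segments are averaged.

## Gaussian-copula MI

Each marginal is mapped through its empirical ranks onto standard
normal quantiles at (r + 0.5)/n; ties are broken by first occurrence
(stable sort), which makes outputs exactly reproducible without random
tie perturbation.  MI in bits is ½·log2[det Σx · det Σy / det Σxy] on
the transformed data.  The analytic Wishart expectation of the
log-determinant is subtracted per entropy term when `bias_correct=True`
(the default), removing the dominant small-sample bias.  Negative
bias-corrected values are *not* clamped inside the estimator — a
clamped estimator cannot average to zero under independence, which is
the calibration property we test — but lag-summed maps clamp at zero on
construction, since MI is non-negative in truth.  The clamp's slight
upward bias on nulls affects both sides of every contrast equally.

The whole-grid code path evaluates the same estimator vectorised over
grid points (ranks along the sample axis, 4×4 joint determinants via
the Schur complement of the shared speech block) and agrees with the
scalar path to ~1e-9 bits; the only discrepancy source is tie ordering
in float32 storage, with effects around 1e-6 bits.

## Speech tracking

Envelope and neural series are filtered per band (third-order
zero-phase Butterworth for every band, including the phoneme band,
where the upstream description specifies the order only for the slower
bands; the order is a configuration knob), Hilbert transformed, and the
first and last 0.5 s of every trial discarded to suppress filter
transients.  For each lag τ ∈ {60, 80, 100, 120, 140} ms the speech
sample at t is paired with the neural sample at t + τ (neural activity
lags the stimulus), the overhang trimmed within trial so no pair spans
a trial boundary, pairs concatenated across trials, real and imaginary
parts z-scored separately, and the 2-D × 2-D copula MI computed; the
five per-lag values are summed.  Summing across lags avoids the
spurious sensitivity of single-lag estimates.

A practical note on lag resolution: within a narrow band a small delay
acts almost as a phase rotation of the analytic signal, to which the
2-D Gaussian MI is insensitive, so the injected lag is only resolvable
in bands whose bandwidth is large relative to 1/lag-step — the
recovery experiment therefore uses the phoneme band (4.4 Hz wide).

**Surrogates.**  Trial-shuffling surrogates permute which speech trial
is paired with which neural trial (derangements only; mismatched
lengths truncated pairwise) and average 50 iterations — averaging
matters because all sentences share one rhythmic structure, so a single
shuffle retains chance dependence.  Time-reversal surrogates recompute
the analytic transform from the reversed filtered envelope (the
zero-phase filter commutes with reversal).

**Condition contrast.**  With unequal correct/incorrect counts
(~70/30), each repeat draws floor(0.8 × smaller count) trials per
condition without replacement, computes per-condition maps, and
averages 20 repeats (50 for the PAC region test).

## Phase-amplitude coupling

Phase is the unit phasor of the phrasal-band analytic signal (cos, sin
as two real columns); power is the squared analytic magnitude of the
beta band (13–30 Hz).  PAC is their 2-D × 1-D copula MI.  Because the
copula is invariant to the monotone square map, amplitude versus power
is immaterial (tested).  Controls: phrasal phase × alpha (8–12 Hz),
phrasal × theta (4–8 Hz), word phase (1.8–3 Hz) × beta.  Filtering and
the Hilbert transform run once per trial and channel; repeated
subsampling only re-ranks cached channels.  Trials are filtered
individually and concatenated afterwards, so trial boundaries do not
leak through the filters.

## Group statistics

Per grid point, a dependent t test compares two per-participant maps;
zero-variance points are forced to t = 0 with a logged warning.
Cluster correction thresholds the t map at the critical Student t
(df = participants − 1, two-tailed α = .05; 2.093 ≈ 2.1 for 20
participants), groups suprathreshold points into connected components
per sign, and compares each observed T_sum with the permutation
distribution of the maximal cluster statistic over random sign-flips of
the participant difference maps (1,000 Monte-Carlo permutations in the
full profile; the sign-flip is the standard exchangeable null for a
paired design, chosen here since only the randomisation engine is
specified upstream).  One-sided tests (used for the whole-grid PAC
contrast, which has a directional hypothesis) take the maximal signed
T_sum.  p-values use the add-one convention (1 + #{perm ≥ obs})/(1 +
n_perm) and can never be exactly zero.  Adjacency is face-adjacency:
neighbours within 1.01 × grid spacing (configurable radius).  Post-hoc
peak tests are Benjamini–Hochberg FDR corrected.

## Synthetic data generator

The generator emulates the study conditions the pipeline was built
for; it is first-class, tested code, not a fixture.

*Corpus.*  90 sentences of seven elements: two three-word phrases
(each ending in a distinct pause) followed by five content words.  The
phrase inter-onset interval is drawn so per-sentence phrase rates are
N(1.0, 0.1) Hz; word-onset geometry realises per-sentence word rates
N(2.4, 0.3) Hz; syllable and phoneme counts subdivide word and syllable
spans targeting N(3.8, 0.4) and N(10.4, 0.8) Hz.  Mean rates land
within two standard errors of the targets (tested).  Durations are
log-normal — positive and right-skewed, matching speech-timing
practice — and word lengths vary more than phrase lengths (c_v roughly
0.5 vs 0.1), preserving the qualitative ordering of the reference
corpus.  Envelopes are sums of sharp-attack (2-sample) exponentially
decaying pulses at every annotated onset, so each onset coincides with
a local envelope rise (tested), and the phrase-final pauses imprint a
phrasal-band spectral peak near 1 Hz (tested).

*Neural trials.*  Every grid point receives independent 1/f noise
(exponent 1.0 by default — a more realistic band-limited null than
white noise).  Effect-region points add the z-scored envelope delayed
by 100 ms, scaled by a label-dependent amplitude SNR (defaults 0.6
correct / 0.2 incorrect).  Coupling-region points add a beta carrier —
noise filtered to 15–28 Hz, inside the beta band but clear of the
alpha edge so the alpha control is not contaminated by filter leakage
— whose amplitude is 1 + depth·cos(phrasal phase of that point's own
series), with default depths 0.8 (correct) / 0 (incorrect).
Correctness labels are independent Bernoulli(0.7) draws; item
difficulty is out of scope.  The default grid is 8×8×8 at 6 mm with a
central 3×3×3 effect block: small enough for minutes-scale runs, large
enough for non-trivial cluster geometry.

What the generator does *not* emulate: acoustic realism (formants,
background noise, the adaptive noise titration that produced ~70 %
accuracy in the reference study — the generator abstracts difficulty
into label-dependent SNR), spatial leakage between grid points
(beamformer point-spread), trial-to-trial nonstationarity, and
physiological artefacts.  Passing recovery tests therefore shows the
pipeline is correct and calibrated under its stated model, not that
real MEG effects of a given size would be detected.

## Problem sizes of the evaluation battery

The calibration/recovery experiments (`speechtrack.evaluation`, also
run by `scripts/acceptance.py`) use these sizes, chosen to finish in
minutes on one core while keeping every statistical conclusion stable
across seeds:

- estimator accuracy: n = 10,000 samples, ρ ∈ {0, 0.3, 0.6, 0.9};
- independence calibration: 200 runs at n = 500;
- cluster false-positive rate: 200 null experiments, 20 virtual
  participants, 6×6×6 lattice, 500 permutations;
- lag recovery: one participant, 2×2×2 grid, 15 trials, phoneme band;
- SNR monotonicity: 10 amplitude levels × 20 replicate datasets;
- effect-region recovery: 20 participants, 8×8×8 grid, 30 trials,
  5 contrast repeats, 200 permutations, incorrect-trial SNR 0;
- PAC detection: 50 simulated experiments, 10 participants each,
  24 trials, two-point grid, coupling isolated (tracking SNR 0 — with
  tracking present the generator produces genuine envelope-mediated
  coupling in the theta control, which is physiologically sensible but
  confounds the control-specificity check).

The full-fidelity profile (`PipelineConfig()`) keeps the reference
iteration counts (50 surrogate shuffles, 20/50/20 contrast repeats,
1,000 permutations); the scaled profile shrinks only iteration counts,
never the scientific parameters.

## Known limitations

- The copula estimator measures the Gaussian dependence of rank-
  transformed signals; dependence invisible to a Gaussian copula
  (e.g. purely tail-based) is underestimated.
- Tie handling differs between the scalar (stable, first-occurrence)
  and the vectorised (introsort) rank paths; with float32 storage this
  produces ~1e-6-bit discrepancies on continuous data.
- The time-reversal surrogate assumes the band filter commutes with
  reversal, which holds exactly only for zero-phase filtering.
- Derangement-based shuffling slightly over-destroys pairing relative
  to uniform permutation; with 50 iterations the effect on the
  surrogate mean is negligible.
- The generator's effect region has sharp boundaries; real effects are
  smooth, so empirical Jaccard overlap on real data would be lower at
  equal sensitivity.
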