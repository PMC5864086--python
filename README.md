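# speechtrack

Analysis toolkit for **perceptually relevant speech tracking**: does
rhythmic brain activity follow the temporal structure of spoken
sentences, and does stronger tracking go along with better
comprehension?

The package is aimed at researchers working with source-localised
M/EEG time series.  Its core quantities:

- **Stimulus-specific frequency bands.**  Instead of generic delta /
  theta bands, analysis bands are derived from the stimulus itself:
  for each linguistic category the per-sentence event rate is
  1 / mean inter-onset interval, and the band is the [min, max] rate
  across the corpus (phrases ≈ 0.6–1.3 Hz, words 1.8–3 Hz, syllables
  2.8–4.8 Hz, phonemes 8–12.4 Hz in the reference corpus).
- **Gaussian-copula mutual information.**  Dependence between the
  band-limited speech envelope and neural signal is
  I(S; N) = ½ log₂ [det Σ_S · det Σ_N / det Σ_SN] after mapping each
  marginal through its ranks onto standard-normal scores — robust,
  bias-corrected, invariant to monotone transforms.  MI is evaluated
  with the speech signal paired at stimulus→brain lags of 60–140 ms
  (20-ms steps) and summed over lags.
- **Surrogate nulls** by trial shuffling (50 averaged derangements) or
  speech time reversal.
- **Condition contrasts** between correctly and incorrectly
  comprehended trials at equalised trial counts (80 % of the smaller
  condition, repeated subsampling).
- **Phase–amplitude coupling**: copula MI between the phrasal-band
  unit phasor (2-D) and beta power (1-D), with alpha / theta /
  word-phase control pairs.
- **Cluster-based permutation statistics** over the source grid
  (dependent t maps, critical t ≈ 2.1 for 20 participants, sign-flip
  permutation of the maximal cluster T_sum) and Benjamini–Hochberg FDR
  for post-hoc tests.

A synthetic-data module generates corpora and multi-participant trial
sets with known ground truth (effect region, tracking lag and SNR, PAC
depth), so the entire pipeline is testable without any recordings.
See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
import numpy as np
from speechtrack import (
    SynthConfig, generate_corpus, generate_participant, prepare_trials,
    rates_from_onsets, derive_band, CANONICAL_BANDS,
    tracking_mi, surrogate_shuffle,
)

cfg = SynthConfig(master_seed=7)          # 90 sentences, 20 participants
annotations, envelopes = generate_corpus(cfg)

for cat in ("phrase", "word", "syllable", "phoneme"):
    summary = rates_from_onsets(annotations, cat)
    band = derive_band(summary)
    print(f"{cat:9s} rate {summary.mean:4.2f} +/- {summary.sd:4.2f} Hz"
          f"  -> band {band.f_lo:.1f}-{band.f_hi:.1f} Hz")

raw = generate_participant(cfg, envelopes, participant=0)
trials = prepare_trials(raw, CANONICAL_BANDS["phrase"])

effect_point = int(cfg.effect_region[0])
mi = tracking_mi(trials, effect_point)            # lag-summed, 60-140 ms
null = surrogate_shuffle(trials, effect_point, n_iter=50, seed=0)
print(f"tracking MI at effect point: {mi.bits:.3f} bits")
print(f"trial-shuffled surrogate:    {null.bits:.3f} bits")
```

Output:

```
phrase    rate 0.99 +/- 0.10 Hz  -> band 0.8-1.2 Hz
word      rate 2.37 +/- 0.31 Hz  -> band 1.6-3.2 Hz
syllable  rate 3.82 +/- 0.40 Hz  -> band 2.8-4.9 Hz
phoneme   rate 10.28 +/- 0.81 Hz  -> band 8.4-12.2 Hz
tracking MI at effect point: 1.389 bits
trial-shuffled surrogate:    0.354 bits
```

The generated corpus reproduces the target rates (1.0 / 2.4 / 3.8 /
10.4 Hz); the grid point inside the synthetic effect region carries
about a bit of lag-summed envelope information above its trial-shuffled
null, which is what the group-level statistics then contrast across
participants and conditions.

The same analyses are scriptable from the shell:

```bash
speechtrack synth   --seed 7 --out data/            # corpus + trial sets
speechtrack bands   data/annotations.tsv            # derived bands
speechtrack run-all --seed 7 --scaled --out results/run/
speechtrack report  results/run/report.json
```

`run-all` executes the full graph — band derivation, per-band tracking
vs surrogate, correct/incorrect contrasts, cluster statistics, peak
post-hocs, the PAC region test with controls, the one-sided whole-grid
PAC contrast and the generic 2-Hz band sweep — and writes maps, cluster
tables and a manifest whose hash is a pure function of the
configuration.

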