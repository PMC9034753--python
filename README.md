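# amtc — temporal coding of amplitude-modulated tones in spike trains

`amtc` is a Python package for analysing extracellular spike-train
recordings from auditory neurons (e.g. inferior-colliculus units) driven by
sinusoidally amplitude-modulated (AM) tones. It is aimed at auditory
neurophysiologists who have spike times per trial and stimulus metadata and
want the standard battery of temporal-coding metrics, plus a fully
specified synthetic spike-train generator so that every stage of the
analysis can be validated against known ground truth.

## What it computes

Spike times (ms re stimulus onset, prestimulus spikes negative) are binned
into peristimulus time histograms (PSTHs) at 200 µs resolution and smoothed
with a Gaussian kernel whose width follows the modulation frequency f_m:

    σ(f_m) = 80 / f_m   [ms]        (e.g. σ = 1 ms at 80 Hz)

Per-unit smoothed PSTHs are superposed into the convolved population PSTH
(CPSTH); its minima around the nominal grid k/f_m segment the response into
modulation periods. On top of this the package computes:

- **Spontaneous rate** (mean ± SD of per-trial rates in the 500-ms
  prestimulus window) — the baseline for all response criteria.
- **Evoked rate per period**: mean PSTH rate per period minus
  (spontaneous mean + 2 SD), clipped at zero.
- **First-spike latency (FSL)**: earliest post-onset bin whose smoothed
  rate exceeds the spontaneous mean + 2 SD and that contains a spike;
  population FSL is the median over units.
- **Vector strength** VS = |Σ e^{iθ_j}|/n of pooled spike phases
  θ_j = 2π f_m t_j, with a Rayleigh test (finite-n corrected,
  p = e^{-Z}(1 + (2Z − Z²)/4n), Z = nVS²) at α = 0.01.
- **NCCH** — normalized cross-correlation histogram between one period of
  the stimulus envelope r[n] and the PSTH,
  NCCH[k] = Σ r[n]·PSTH[n+k] / √(Σ r[n]² · Σ PSTH[n+k]²) ∈ [0, 1].
- **PCH** — the offset-corrected, Pearson-like variant using the zero-mean
  reference s[n] = r[n] − r̄ and mean-subtracted PSTH, ∈ [−1, 1]. A flat
  response gives PCH = 0 where NCCH still reports 1/√1.5 ≈ 0.817 — the
  reason the offset-corrected coefficient is the preferred fidelity metric.
- **CC_NC / CC_PC**: per-period peak coefficients of NCCH/PCH averaged over
  the M analysed periods and scaled by √M, making values comparable across
  modulation frequencies.
- **Peak latency and jitter**: per-period position of the correlation
  maximum relative to the stimulus period start (mean ± SD over periods);
  latencies beyond one modulation period are resolved against the onset
  response, so dimensionless latencies (latency × f_m / 1000) above 1 are
  representable.
- **Tuning curves**: characteristic frequency (CF), threshold at CF
  (criterion: spontaneous mean + 3 SD) and Q40 = CF / bandwidth at
  threshold + 40 dB.
- **Group statistics**: two-tailed Mann–Whitney U tests (exact for small
  tie-free samples), medians and fold changes.

The synthetic generator (`amtc.synth`) emulates the recording protocol —
15 trials per condition, 500-ms AM tones at 70 dB SPL with 100% depth, f_m
= 10–160 Hz in 10-Hz steps, 500-ms prestimulus window, carrier at the
unit's best frequency — with per-period Gaussian response bumps of known
latency and jitter, onset adaptation, a Poisson spontaneous floor, and
"wt"/"ko" group presets that mimic a wild-type vs knockout contrast
(higher spontaneous rate, lower evoked rate, longer latency and strong
high-f_m jitter growth in the knockout).

## Worked example

```sh
amtc simulate --preset wt --units 8 --seed 7 --out demo/data
printf 'fm_ladder: [50.0, 100.0]\n' > demo/config.yaml
amtc analyze --spikes demo/data/spikes.csv --stimuli demo/data/stimuli.json \
             --config demo/config.yaml --out demo/results
amtc report --results demo/results --format md
```

which prints

```
| group   |   mod_hz |   n_units |   peak_latency_ms |   jitter_ms |   peak_latency_periods |
|:--------|---------:|----------:|------------------:|------------:|-----------------------:|
| wt      |       50 |         8 |             11.83 |        0.78 |                 0.5917 |
| wt      |      100 |         8 |             12.19 |        0.21 |                 1.219  |
```

The wild-type preset imposes a ~12-ms response peak latency; the population
analysis recovers 11.83 ms at f_m = 50 Hz (0.59 modulation periods) and
12.19 ms at 100 Hz — more than one full period (1.22), which the
onset-anchored unwrapping resolves correctly. The jitter column is the SD
of per-period peak latencies. `demo/results/` also contains
`unit_metrics.tsv` (per-unit spontaneous rates, FSL, vector strength,
Rayleigh p, CC_NC, CC_PC), `population_metrics.tsv`, `evoked_rates.tsv`
and `group_comparisons.tsv`.

The same analyses are available as library functions (`amtc.bin_psth`,
`amtc.population_cpsth`, `amtc.segment_periods`, `amtc.vector_strength`,
`amtc.ncch`, `amtc.pch`, `amtc.run_pipeline`, …); see the module
docstrings.

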