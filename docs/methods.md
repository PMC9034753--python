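# Methods

This note documents the analysis model, its tunable parameters, the
synthetic-data model used for validation, and the numerical and design
choices made where the procedure was genuinely open.

## Analysis model

**Time base.** All spike times are milliseconds relative to stimulus
onset; the prestimulus window carries negative times. All histograms use a
fixed 200-µs bin with left-closed intervals: a spike exactly on a bin edge
belongs to the bin starting there. PSTH values are spikes/s averaged over
trials.

**Kernel.** Smoothing uses a Gaussian kernel with σ(f_m) = 80/f_m ms —
broad smoothing for slow modulations, fine resolution for fast ones
(σ = 8 ms at 10 Hz down to 0.5 ms at 160 Hz). The discrete kernel is
truncated at ±4σ and renormalized to unit area on the grid; boundaries use
symmetric reflection, which conserves total area exactly. σ below half a
bin triggers a warning (the kernel is still normalized). Responses to
unmodulated tones, for which σ(f_m) is undefined, use a fixed 1-ms kernel.

**Population CPSTH.** Per-unit raw PSTHs are smoothed and *summed* across
units. "Superposition" was read as summation, not averaging; a per-unit
mean is available (`average=True`) for comparing populations of unequal
size. All correlation metrics are invariant to this choice; evoked rates
use the per-unit mean explicitly.

**Period segmentation.** Nominal period boundaries lie at k/f_m. Each
boundary is moved to the CPSTH minimum within ±25% of one period around
the nominal position (ties → earliest bin). The bounded search prevents
period merging/skipping; a flat CPSTH falls back to the nominal grid and
is flagged. The default analysis window excludes the first 100 ms of the
response to avoid onset distortions, leaving 400 ms (M = 0.4·f_m periods).

**Criteria relative to spontaneous activity.** The spontaneous rate of a
unit/condition is the mean of per-trial prestimulus rates; the SD in every
"+2 SD" / "+3 SD" criterion is the sample SD (ddof = 1) of those per-trial
rates — the only SD computable per unit and condition. Evoked rates are
clipped at zero.

**First-spike latency.** The verbal rule "the first spike that exceeds
the spontaneous rate by 2 SD" mixes an event with a rate criterion; it is
made well-defined by requiring both: FSL is the start of the earliest
post-onset bin whose *smoothed* rate exceeds the criterion **and** that
contains at least one raw spike. Units with no qualifying bin have
undefined FSL and are excluded (and counted) from the population median.

**Correlation histograms.** The reference r[n] is one period of the
100%-depth sinusoidal envelope sampled on the 200-µs grid, minimum at the
period start. The NCCH denominator Σ(PSTH[n])² is evaluated over the N
samples of the sliding window at each lag (standard normalized
cross-correlation); a fixed global norm would not bound the histogram by 1
at every lag. Zero-energy (NCCH) or zero-variance (PCH) windows map to 0
and are flagged rather than raising — flat responses are expected at high
f_m. The PCH subtracts the PSTH mean over the whole analysed window, per
the Pearson-like definition.

**Peak latency convention.** The reference peaks half a period after its
start, so the correlation maximum at alignment lag ℓ corresponds to a
response maximum at ℓ + T/2 within the stimulus period. Reported peak
latencies are these response-peak positions, measured from the start of
the stimulus cycle (the nominal multiple of T containing the segmented
period), with the integer number of periods resolved against the delay of
the *first* onset bump (earliest 60%-range crossing of the smoothed trace,
climbed to its local maximum — robust when onset adaptation is weak and a
later bump fluctuates higher). This makes latencies up to ~2 periods
representable, as observed at high modulation frequencies where the
dimensionless latency (latency·f_m/1000) exceeds 1. Periods whose full lag
range is not covered by the histogram (the last periods of the window) are
skipped. Jitter is the sample SD of per-period latencies; "mean peak
latency" averages per-unit latencies instead (population vs unit mode are
both computed).

**Rayleigh test.** p = e^{−Z}(1 + (2Z − Z²)/4n) with Z = nVS², clamped to
(0, 1]; significance at α = 0.01. The finite-n correction keeps the type-I
error near nominal for the spike counts encountered here (calibration is
part of the acceptance suite).

**Tuning curves.** CF = frequency whose lowest level with rate >
spontaneous mean + 3 SD is minimal (ties → higher rate at threshold, then
lower frequency). Q40 is evaluated 40 dB above the threshold *at CF* (the
only dimensionally sensible reading of "40 dB above the CF"); band edges
are refined by linear interpolation in log₂ frequency between the last
sub-criterion and first supra-criterion grid points, because 16
frequencies over six octaves are too coarse for raw-grid bandwidths.
Q40 is undefined (flagged, not an error) when the evaluation level exceeds
the 70-dB grid ceiling or the response touches a frequency edge of the
grid. Thresholds are reported at grid resolution (no sub-10-dB
interpolation).

**Group statistics.** Two-tailed Mann–Whitney U throughout, α = 0.05, no
multiple-testing correction by default (a Bonferroni switch exists). The
null distribution is exact (full enumeration) when min(n, m) ≤ 8 and the
pooled sample is tie-free; otherwise the normal approximation with tie and
continuity correction is used. Fold changes are ratios of medians reported
to 2 decimals.

## Synthetic-data model

Each synthetic unit is: (1) a homogeneous Poisson spontaneous floor over
the full recorded window; (2) per modulation period p, a Poisson number of
evoked spikes with mean `evoked_spikes_per_period × (1 + (onset_gain − 1)
e^{−p/decay})`, each placed at `period_start + peak_latency + N(0, jitter)`
with probability `lock_fraction`, else uniformly within the period. Evoked
spikes are confined to the stimulus (negative jitter draws before t = 0
are discarded, not wrapped). The per-period Gaussian bump — rather than a
rectified-sinusoid rate — gives direct ground truth for exactly the
quantities the analysis measures (peak latency, jitter); onset adaptation
reproduces the elevated first-period rates. Jitter may grow linearly with
f_m above a knee frequency (`jitter_slope_ms_per_100hz`, `jitter_knee_hz`),
the mechanism behind the knockout preset's high-f_m decoherence. Pure-tone
responses scale a Poisson driven rate by a Gaussian in octave distance
from the unit's best frequency; tuning responses use a V-shaped threshold
(flank slopes in dB/octave) with a 2-dB logistic level dependence, chosen
so sub-threshold levels stay below the 3-SD criterion while the threshold
level itself responds at half the maximal rate. Flank slopes default to
50–60 dB/octave, putting Q40 near 0.9 (broadly tuned midbrain units).

Seeding is hierarchical (`numpy.random.SeedSequence`): master →
per-unit → per-condition → per-trial streams, so any subset of the data is
reproducible in isolation.

**Group presets.** The wild-type preset uses a log-normal spontaneous-rate
distribution with median 0.49 spikes/s, ~1.2 evoked spikes/period, 12 ± 1
ms peak latency and ~1 ms jitter. The knockout preset has median 1.02
spikes/s spontaneous rate (≈2.1-fold higher), lower evoked rate
(0.8/period), +2.5 ms peak latency with larger unit-to-unit spread, lower
lock fraction, and jitter growing at 8 ms per 100 Hz above 60 Hz — i.e.
jitter becomes comparable to the modulation period at high f_m, the
physical regime in which phase locking collapses. These magnitudes encode
only the qualitative genotype contrasts; no quantitative jitter values
exist to target.

**What the generator does not emulate.** No refractoriness or spike-sorting
contamination; no carrier-frequency acoustics (the carrier matters only
through the best-frequency bookkeeping); the unlocked evoked component is
uniform over the whole period, so preset cohorts produce very short FSLs
(stray early spikes satisfy the criterion when the spontaneous SD is
small) — the FSL estimator itself is validated separately on fully locked
cohorts, where it recovers imposed latencies within 1 ms. Passing tests on
synthetic data therefore demonstrate correctness of the measurement
pipeline under the stated response model, not robustness to every
real-recording artifact.

## Problem sizes and tolerances used in validation

Parameter recovery uses 100-unit cohorts, 15 trials, f_m = 50 Hz, imposed
peak latencies 15/18/21 ms (21 ms exceeds the 20-ms period) under
low-noise measurement-fidelity conditions (0.25-ms jitter, full locking,
1-Hz spontaneous floor): population peak latency within 0.5 ms, median FSL
within 1 ms. Rayleigh calibration uses 1000 uniform-phase sets of 100
spikes, with the rejection count checked against the exact binomial 99%
interval. The genotype-contrast suite uses 50 units per preset across
f_m = 80–160 Hz. Monte-Carlo expectations (spontaneous-rate recovery) are
asserted within 3 SE of their analytic values. The Mann–Whitney exact path
is checked against full enumeration of all equal-size rank layouts up to
n = m = 6.

## Known limitations

- Period-boundary placement is limited to ±25% of a period; responses
  whose minima drift farther (latency near half a period plus jitter) pin
  boundaries at the search edge. Peak latencies are measured from nominal
  cycle starts, so this does not bias latency.
- The onset-anchored period unwrapping assumes a detectable onset response
  within the first ~2.5 periods; without one, latencies default to the
  [T/2, 3T/2) branch.
- The NCCH normalization is one of two readings of the defining formula
  (sliding-window vs global denominator); the windowed form is the default
  because it bounds the histogram at every lag, and a ``normalization=
  "global"`` switch is provided for comparison. On the synthetic responses
  tested, the per-period peak *locations* of the two modes agree to within
  the bin resolution.
- No adaptive kernel bandwidth, spike-distance latency estimators, or
  Fourier modulation-transfer functions; these are out of scope.
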