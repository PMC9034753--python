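"""Synthetic spike-train generator emulating the AM-tone recording protocol.

The generator produces the statistical structure the analysis assumes,
with known ground truth for every quantity the pipeline measures:

* a homogeneous Poisson *spontaneous* floor over the whole recorded window
  (500-ms prestimulus + stimulus);
* a *phase-locked evoked* process: per modulation period, a Poisson number
  of spikes placed at ``period_start + peak_latency + N(0, jitter)`` with
  probability ``lock_fraction`` (otherwise uniform within the period), with
  an exponentially decaying onset gain over the first periods (adaptation);
* pure-tone responses whose driven rate falls off as a Gaussian in octave
  distance from the unit's best frequency (for best-frequency recovery);
* V-shaped tuning receptive fields on a frequency x level grid (for
  CF / threshold / Q40 recovery).

Two group presets mimic the study's genotypes: the knockout ("ko") preset
has a higher spontaneous rate, a lower evoked rate, 2-3 ms longer peak
latency, and jitter that grows steeply with modulation frequency above
~60 Hz, while the wild-type ("wt") preset stays temporally precise.

The default stimulus protocol is the study's: 15 trials per condition,
500-ms AM tones at 70 dB SPL, 100% sinusoidal depth, f_m from 10 to 160 Hz
in 10-Hz steps, 500-ms prestimulus window, carrier at the unit's best
frequency; 200-ms pure tones on a 16-frequency log grid; 100-ms tuning
tones on a 16 x 8 frequency-level grid with 10 repetitions.

Seeding is hierarchical (``numpy.random.SeedSequence``): one master seed
spawns per-unit streams, which spawn per-condition and per-trial streams,
so any granularity is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel import StimulusKind, StimulusSpec, TrialSpikes, UnitRecording

__all__ = [
    "SyntheticUnitParams",
    "GroupPreset",
    "TuningParams",
    "WT_PRESET",
    "KO_PRESET",
    "PRESETS",
    "am_ladder",
    "pt_ladder",
    "tuning_grid",
    "gen_am_trial",
    "gen_pt_trial",
    "gen_unit",
    "gen_cohort",
    "gen_tuning_unit",
]

#: the study's pure-tone / tuning frequency grid: 16 log-spaced, 1-64 kHz
PT_FREQS_HZ = tuple(float(f) for f in
                    np.round(1000.0 * 2.0 ** (np.arange(16) * 6.0 / 15.0)))
#: tuning-curve level grid, dB SPL
TUNING_LEVELS_DB = tuple(float(l) for l in range(0, 80, 10))
#: best-frequency choices used by the cohort presets: the subset of the
#: 16-frequency protocol grid within ~3-16 kHz, so that a unit's AM carrier
#: (= its BF) is also a pure-tone ladder frequency
BF_CHOICES_HZ = tuple(f for f in PT_FREQS_HZ if 3000.0 <= f <= 16000.0)


@dataclass(frozen=True)
class SyntheticUnitParams:
    """Ground-truth response parameters of one synthetic unit."""

    spont_rate_hz: float = 0.5
    evoked_spikes_per_period: float = 1.2
    onset_gain: float = 2.5
    onset_decay_periods: float = 3.0
    peak_latency_ms: float = 12.0
    jitter_ms: float = 1.0
    latency_slope_ms_per_100hz: float = 0.0
    jitter_slope_ms_per_100hz: float = 0.0
    jitter_knee_hz: float = 60.0
    lock_fraction: float = 0.85
    bf_hz: float = 11310.0
    pt_evoked_rate_hz: float = 40.0
    pt_tuning_sd_oct: float = 0.7
    pt_latency_ms: float = 8.0

    def __post_init__(self) -> None:
        if self.spont_rate_hz < 0 or self.evoked_spikes_per_period < 0:
            raise ValueError("rates must be nonnegative")
        if self.onset_gain < 1:
            raise ValueError("onset_gain must be >= 1")
        if self.jitter_ms < 0:
            raise ValueError("jitter_ms must be >= 0")
        if not 0.0 <= self.lock_fraction <= 1.0:
            raise ValueError("lock_fraction must be in [0, 1]")

    def latency_at(self, mod_hz: float) -> float:
        return self.peak_latency_ms + self.latency_slope_ms_per_100hz * mod_hz / 100.0

    def jitter_at(self, mod_hz: float) -> float:
        extra = max(0.0, mod_hz - self.jitter_knee_hz) / 100.0
        return self.jitter_ms + self.jitter_slope_ms_per_100hz * extra


@dataclass(frozen=True)
class GroupPreset:
    """Distribution from which a cohort's unit parameters are drawn.

    Gaussian per-field spread around the stated means (clipped to valid
    ranges); the spontaneous rate is log-normal with the stated *median* so
    the cohort median matches the preset directly.
    """

    name: str
    spont_rate_median_hz: float
    spont_rate_log_sd: float = 1.1
    evoked_mean: float = 1.2
    evoked_sd: float = 0.3
    onset_gain_mean: float = 2.5
    onset_gain_sd: float = 0.5
    onset_decay_periods: float = 3.0
    peak_latency_mean_ms: float = 12.0
    peak_latency_sd_ms: float = 1.0
    latency_slope_ms_per_100hz: float = 0.0
    jitter_mean_ms: float = 1.0
    jitter_sd_ms: float = 0.3
    jitter_slope_ms_per_100hz: float = 0.5
    jitter_knee_hz: float = 60.0
    lock_fraction_mean: float = 0.85
    lock_fraction_sd: float = 0.08
    pt_evoked_rate_hz: float = 40.0
    pt_tuning_sd_oct: float = 0.7
    bf_choices_hz: tuple[float, ...] = BF_CHOICES_HZ

    def draw(self, rng: np.random.Generator) -> SyntheticUnitParams:
        g = rng.normal
        return SyntheticUnitParams(
            spont_rate_hz=float(self.spont_rate_median_hz
                                * np.exp(rng.normal(0.0, self.spont_rate_log_sd))),
            evoked_spikes_per_period=max(0.05, g(self.evoked_mean, self.evoked_sd)),
            onset_gain=max(1.0, g(self.onset_gain_mean, self.onset_gain_sd)),
            onset_decay_periods=self.onset_decay_periods,
            peak_latency_ms=max(2.0, g(self.peak_latency_mean_ms,
                                       self.peak_latency_sd_ms)),
            jitter_ms=max(0.1, g(self.jitter_mean_ms, self.jitter_sd_ms)),
            latency_slope_ms_per_100hz=self.latency_slope_ms_per_100hz,
            jitter_slope_ms_per_100hz=self.jitter_slope_ms_per_100hz,
            jitter_knee_hz=self.jitter_knee_hz,
            lock_fraction=float(np.clip(g(self.lock_fraction_mean,
                                          self.lock_fraction_sd), 0.0, 1.0)),
            bf_hz=float(rng.choice(self.bf_choices_hz)),
            pt_evoked_rate_hz=self.pt_evoked_rate_hz,
            pt_tuning_sd_oct=self.pt_tuning_sd_oct,
        )


# The knockout preset differs from wild-type in the directions reported for
# the study's genotypes: ~2-fold higher spontaneous rate, lower evoked rate,
# +2.5 ms peak latency with larger unit-to-unit spread, and jitter growing
# toward the modulation period above ~60 Hz (temporal decoherence at high
# f_m); wild-type jitter stays near 1 ms across the ladder.
WT_PRESET = GroupPreset(name="wt", spont_rate_median_hz=0.49)
KO_PRESET = GroupPreset(
    name="ko",
    spont_rate_median_hz=1.02,
    evoked_mean=0.8,
    evoked_sd=0.25,
    peak_latency_mean_ms=14.5,
    peak_latency_sd_ms=3.0,
    jitter_mean_ms=1.3,
    jitter_sd_ms=0.4,
    jitter_slope_ms_per_100hz=8.0,
    jitter_knee_hz=50.0,
    lock_fraction_mean=0.75,
    pt_evoked_rate_hz=30.0,
)
PRESETS = {"wt": WT_PRESET, "ko": KO_PRESET}


@dataclass(frozen=True)
class TuningParams:
    """V-shaped receptive field: threshold rises from ``threshold_db`` at
    the characteristic frequency along both flanks (dB per octave)."""

    cf_hz: float = 11310.0
    threshold_db: float = 20.0
    # ~50-60 dB/oct flanks put Q40 near 0.9 (broadly tuned midbrain units)
    slope_lo_db_per_oct: float = 50.0
    slope_hi_db_per_oct: float = 60.0
    max_rate_hz: float = 50.0
    spont_rate_hz: float = 0.5

    def threshold_at(self, freq_hz: float) -> float:
        oct_dist = np.log2(freq_hz / self.cf_hz)
        slope = self.slope_hi_db_per_oct if oct_dist >= 0 else self.slope_lo_db_per_oct
        rise = 0.0 if oct_dist == 0 else slope * abs(oct_dist)  # guards inf * 0
        return float(self.threshold_db + rise)

    def driven_rate(self, freq_hz: float, level_db: float,
                    scale_db: float = 2.0) -> float:
        """Logistic level dependence around the V-shaped threshold."""
        thr = self.threshold_at(freq_hz)
        if np.isinf(thr):
            return 0.0
        return float(self.max_rate_hz / (1.0 + np.exp(-(level_db - thr) / scale_db)))


# ---------------------------------------------------------------------------
# stimulus protocols

def am_ladder(
    carrier_hz: float = 11310.0,
    mod_hz_values: Sequence[float] = tuple(range(10, 170, 10)),
    n_trials: int = 15,
    duration_ms: float = 500.0,
    prestim_ms: float = 500.0,
    level_db_spl: float = 70.0,
) -> dict[str, StimulusSpec]:
    """The study's AM protocol: 500-ms tones, 100% depth, f_m 10-160 Hz."""
    out = {}
    for fm in mod_hz_values:
        cid = f"am_{int(round(carrier_hz))}_{int(round(fm)):03d}"
        out[cid] = StimulusSpec(
            condition_id=cid, kind=StimulusKind.AM, carrier_hz=carrier_hz,
            mod_hz=float(fm), depth=1.0, level_db_spl=level_db_spl,
            duration_ms=duration_ms, rise_fall_ms=5.0, n_trials=n_trials,
            prestim_ms=prestim_ms,
        )
    return out


def pt_ladder(
    freqs_hz: Sequence[float] = PT_FREQS_HZ,
    n_trials: int = 15,
    duration_ms: float = 200.0,
    prestim_ms: float = 500.0,
    level_db_spl: float = 70.0,
) -> dict[str, StimulusSpec]:
    """Pure-tone protocol for best-frequency determination."""
    return {
        f"pt_{int(round(f))}": StimulusSpec(
            condition_id=f"pt_{int(round(f))}", kind=StimulusKind.PT,
            carrier_hz=float(f), mod_hz=0.0, depth=0.0,
            level_db_spl=level_db_spl, duration_ms=duration_ms,
            rise_fall_ms=5.0, n_trials=n_trials, prestim_ms=prestim_ms,
        )
        for f in freqs_hz
    }


def tuning_grid(
    freqs_hz: Sequence[float] = PT_FREQS_HZ,
    levels_db: Sequence[float] = TUNING_LEVELS_DB,
    n_trials: int = 10,
    duration_ms: float = 100.0,
    prestim_ms: float = 100.0,
) -> dict[str, StimulusSpec]:
    """Tuning protocol: 16 log-spaced frequencies x 0-70 dB in 10-dB steps."""
    out = {}
    for f in freqs_hz:
        for lv in levels_db:
            cid = f"tc_{int(round(f))}_{int(round(lv)):02d}"
            out[cid] = StimulusSpec(
                condition_id=cid, kind=StimulusKind.TUNING,
                carrier_hz=float(f), mod_hz=0.0, depth=0.0,
                level_db_spl=float(lv), duration_ms=duration_ms,
                rise_fall_ms=5.0, n_trials=n_trials, prestim_ms=prestim_ms,
            )
    return out


# ---------------------------------------------------------------------------
# trial generators

def _spont_spikes(rate_hz: float, t0_ms: float, t1_ms: float,
                  rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate_hz * (t1_ms - t0_ms) * 1e-3)
    return rng.uniform(t0_ms, t1_ms, size=n)


def gen_am_trial(
    params: SyntheticUnitParams,
    stim: StimulusSpec,
    seed: int | np.random.Generator,
) -> TrialSpikes:
    """One trial of the AM response model (see module docstring)."""
    if stim.kind != StimulusKind.AM or stim.mod_hz <= 0:
        raise ValueError("gen_am_trial requires an AM condition with mod_hz > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    period = stim.period_ms
    n_periods = int(np.floor(stim.duration_ms / period + 1e-9))
    latency = params.latency_at(stim.mod_hz)
    jitter = params.jitter_at(stim.mod_hz)

    spikes = [_spont_spikes(params.spont_rate_hz, -stim.prestim_ms,
                            stim.duration_ms, rng)]
    p_idx = np.arange(n_periods)
    gain = 1.0 + (params.onset_gain - 1.0) * np.exp(-p_idx / params.onset_decay_periods)
    counts = rng.poisson(params.evoked_spikes_per_period * gain)
    for p, c in zip(p_idx, counts):
        if c == 0:
            continue
        start = p * period
        locked = rng.random(c) < params.lock_fraction
        t = np.where(
            locked,
            start + latency + rng.normal(0.0, jitter, size=c),
            start + rng.uniform(0.0, period, size=c),
        )
        spikes.append(t)
    t = np.concatenate(spikes)
    # evoked spikes are confined to the stimulus; negative jitter draws may
    # precede the period start but never the stimulus onset (not wrapped)
    keep = (t >= -stim.prestim_ms) & (t < stim.duration_ms)
    pre = t[keep & (t < 0)]
    ev = t[keep & (t >= 0)]
    t = np.sort(np.concatenate([pre, ev]))
    return TrialSpikes("", stim.condition_id, 0, t)


def gen_pt_trial(
    params: SyntheticUnitParams,
    stim: StimulusSpec,
    seed: int | np.random.Generator,
) -> TrialSpikes:
    """One pure-tone trial: Poisson driven rate scaled by octave distance
    of the carrier from the unit's best frequency."""
    if stim.kind != StimulusKind.PT:
        raise ValueError("gen_pt_trial requires a PT condition")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    oct_dist = np.log2(stim.carrier_hz / params.bf_hz)
    rate = params.pt_evoked_rate_hz * np.exp(
        -0.5 * (oct_dist / params.pt_tuning_sd_oct) ** 2
    )
    spikes = [_spont_spikes(params.spont_rate_hz, -stim.prestim_ms,
                            stim.duration_ms, rng)]
    t0 = min(params.pt_latency_ms, stim.duration_ms)
    n = rng.poisson(rate * (stim.duration_ms - t0) * 1e-3)
    spikes.append(rng.uniform(t0, stim.duration_ms, size=n))
    t = np.sort(np.concatenate(spikes))
    return TrialSpikes("", stim.condition_id, 0, t)


def gen_unit(
    preset_or_params: GroupPreset | SyntheticUnitParams,
    stimuli: dict[str, StimulusSpec],
    seed: int | np.random.SeedSequence,
    unit_id: str = "u0",
    group: Optional[str] = None,
) -> tuple[UnitRecording, SyntheticUnitParams]:
    """Generate one unit over all given conditions; deterministic in ``seed``.

    A :class:`GroupPreset` draws the unit's parameters once from the preset;
    passing :class:`SyntheticUnitParams` uses them as-is. Returns the
    recording together with the ground-truth parameters.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    param_seed, trial_seed = ss.spawn(2)
    if isinstance(preset_or_params, GroupPreset):
        params = preset_or_params.draw(np.random.default_rng(param_seed))
        grp = group if group is not None else preset_or_params.name
    else:
        params = preset_or_params
        grp = group if group is not None else ""
    rec = UnitRecording(unit_id=unit_id, group=grp,
                        best_frequency_hz=params.bf_hz)
    cids = sorted(stimuli)
    streams = trial_seed.spawn(len(cids))
    for cid, cstream in zip(cids, streams):
        stim = stimuli[cid]
        trial_streams = cstream.spawn(stim.n_trials)
        trials = []
        for k, tstream in enumerate(trial_streams):
            rng = np.random.default_rng(tstream)
            if stim.kind == StimulusKind.AM:
                tr = gen_am_trial(params, stim, rng)
            else:
                tr = gen_pt_trial(params, stim, rng)
            trials.append(TrialSpikes(unit_id, cid, k, tr.spike_times_ms))
        rec.trials[cid] = trials
    return rec, params


def gen_cohort(
    preset: GroupPreset,
    n_units: int,
    seed: int,
    mod_hz_values: Sequence[float] = tuple(range(10, 170, 10)),
    include_pt: bool = False,
    n_trials: int = 15,
) -> tuple[dict[str, UnitRecording], dict[str, StimulusSpec],
           dict[str, SyntheticUnitParams]]:
    """Generate a cohort: per-unit parameters drawn from the preset, the AM
    ladder carried at each unit's best frequency (and optionally the PT
    ladder). Returns (units, stimuli, ground-truth params per unit)."""
    ss = np.random.SeedSequence(seed)
    unit_streams = ss.spawn(n_units)
    units: dict[str, UnitRecording] = {}
    stimuli: dict[str, StimulusSpec] = {}
    truth: dict[str, SyntheticUnitParams] = {}
    pt = pt_ladder(n_trials=n_trials) if include_pt else {}
    stimuli.update(pt)
    for i, ustream in enumerate(unit_streams):
        uid = f"{preset.name}{i:03d}"
        # peek the unit's BF so its AM ladder uses the right carrier
        params = preset.draw(np.random.default_rng(ustream.spawn(2)[0]))
        ladder = am_ladder(carrier_hz=params.bf_hz, mod_hz_values=mod_hz_values,
                           n_trials=n_trials)
        stimuli.update({k: v for k, v in ladder.items() if k not in stimuli})
        rec, params = gen_unit(params, {**ladder, **pt},
                               seed=ustream, unit_id=uid, group=preset.name)
        rec.best_frequency_hz = params.bf_hz
        units[uid] = rec
        truth[uid] = params
    return units, stimuli, truth


def gen_tuning_unit(
    tparams: TuningParams,
    stimuli: dict[str, StimulusSpec],
    seed: int,
    unit_id: str = "u0",
    group: str = "",
) -> UnitRecording:
    """Generate tuning-grid responses from a V-shaped receptive field."""
    ss = np.random.SeedSequence(seed)
    rec = UnitRecording(unit_id=unit_id, group=group)
    cids = sorted(stimuli)
    streams = ss.spawn(len(cids))
    for cid, cstream in zip(cids, streams):
        stim = stimuli[cid]
        if stim.kind != StimulusKind.TUNING:
            raise ValueError(f"condition {cid!r} is not a TUNING condition")
        rate = tparams.driven_rate(stim.carrier_hz, stim.level_db_spl)
        trial_streams = cstream.spawn(stim.n_trials)
        trials = []
        for k, tstream in enumerate(trial_streams):
            rng = np.random.default_rng(tstream)
            spont = _spont_spikes(tparams.spont_rate_hz, -stim.prestim_ms,
                                  stim.duration_ms, rng)
            n = rng.poisson(rate * stim.duration_ms * 1e-3)
            driven = rng.uniform(0.0, stim.duration_ms, size=n)
            t = np.sort(np.concatenate([spont, driven]))
            trials.append(TrialSpikes(unit_id, cid, k, t))
        rec.trials[cid] = trials
    return rec
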