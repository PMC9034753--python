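"""Spontaneous rate, per-period evoked rate, first-spike latency, best frequency.

All criteria are expressed relative to the unit's spontaneous activity in the
prestimulus window: a response is called evoked when it exceeds the mean
prestimulus rate by 2 SDs (3 SDs for tuning curves, see :mod:`amtc.tuning`),
where the SD is taken over per-trial prestimulus rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel import StimulusKind, StimulusSpec, UnitRecording
from .psth import BIN_MS, PeriodSegmentation, SmoothedPSTH, bin_psth, convolve, kernel_sigma

__all__ = [
    "SpontStats",
    "spontaneous_stats",
    "evoked_rate_per_period",
    "first_spike_latency",
    "population_fsl",
    "best_frequency",
]

#: kernel SD (ms) used to smooth responses to unmodulated tones, for which
#: sigma = 80 / f_m is undefined
PT_SIGMA_MS = 1.0


@dataclass(frozen=True)
class SpontStats:
    """Mean and SD (over trials) of the prestimulus firing rate, spikes/s."""

    mean_rate_hz: float
    sd_rate_hz: float

    @property
    def criterion_2sd(self) -> float:
        return self.mean_rate_hz + 2.0 * self.sd_rate_hz

    @property
    def criterion_3sd(self) -> float:
        return self.mean_rate_hz + 3.0 * self.sd_rate_hz


def spontaneous_stats(unit: UnitRecording, stim: StimulusSpec) -> SpontStats:
    """Per-trial prestimulus rates -> mean and sample SD across trials."""
    if stim.prestim_ms <= 0:
        raise ValueError(
            f"condition {stim.condition_id!r} has no prestimulus window"
        )
    window_s = stim.prestim_ms * 1e-3
    rates = []
    for t in unit.spikes(stim.condition_id):
        n = int(np.count_nonzero((t >= -stim.prestim_ms) & (t < 0)))
        rates.append(n / window_s)
    rates = np.asarray(rates)
    sd = float(np.std(rates, ddof=1)) if rates.size > 1 else 0.0
    return SpontStats(float(np.mean(rates)), sd)


def evoked_rate_per_period(
    psth_raw: SmoothedPSTH,
    segmentation: PeriodSegmentation,
    spont: SpontStats,
) -> np.ndarray:
    """Mean PSTH rate per period minus (spont mean + 2 SD), clipped at 0."""
    rates = np.empty(segmentation.n_periods)
    for i, (a, b) in enumerate(segmentation.periods()):
        seg = psth_raw.window(a, b)
        mean_rate = float(np.mean(seg)) if seg.size else 0.0
        rates[i] = mean_rate - spont.criterion_2sd
    return np.clip(rates, 0.0, None)


def first_spike_latency(
    unit: UnitRecording,
    stim: StimulusSpec,
    spont: SpontStats,
    sigma_ms: Optional[float] = None,
) -> Optional[float]:
    """First-spike latency of one unit for one condition, in ms.

    The FSL is the start time of the earliest post-onset 200-us bin whose
    rate in the unit's Gaussian-smoothed PSTH exceeds the spontaneous mean
    plus 2 SDs *and* that contains at least one actual spike in the raw
    PSTH. Returns None when no bin within the stimulus qualifies.
    """
    if sigma_ms is None:
        sigma_ms = kernel_sigma(stim.mod_hz) if stim.mod_hz > 0 else PT_SIGMA_MS
    raw = bin_psth(unit.spikes(stim.condition_id),
                   window=(-stim.prestim_ms, stim.duration_ms))
    smooth = convolve(raw, sigma_ms)
    i_on = raw.index_of(0.0)
    qualifies = (smooth.values[i_on:] > spont.criterion_2sd) & (raw.values[i_on:] > 0)
    hits = np.nonzero(qualifies)[0]
    if hits.size == 0:
        return None
    return float(hits[0] * BIN_MS)


def population_fsl(unit_fsls: Sequence[Optional[float]]) -> tuple[float, int]:
    """Median over defined unit FSLs; returns (median_ms, n_undefined)."""
    defined = [x for x in unit_fsls if x is not None and not math.isnan(x)]
    n_undef = len(unit_fsls) - len(defined)
    if not defined:
        raise ValueError("population FSL requires at least one defined FSL")
    return float(np.median(defined)), n_undef


def best_frequency(
    unit: UnitRecording,
    pt_stimuli: Sequence[StimulusSpec],
    spont: SpontStats,
) -> Optional[float]:
    """Best frequency from a pure-tone ladder at fixed level.

    The driven rate of each PT condition is the mean firing rate over the
    full stimulus; BF is the carrier frequency maximizing the
    spontaneous-corrected rate, provided the driven rate exceeds the
    spontaneous mean + 2 SD anywhere; ties break toward the lower frequency.
    """
    best: tuple[float, float] | None = None  # (rate, freq)
    for stim in pt_stimuli:
        if stim.kind != StimulusKind.PT:
            raise ValueError(f"condition {stim.condition_id!r} is not a PT condition")
        dur_s = stim.duration_ms * 1e-3
        counts = [
            np.count_nonzero((t >= 0) & (t < stim.duration_ms))
            for t in unit.spikes(stim.condition_id)
        ]
        driven = float(np.mean(counts)) / dur_s
        if driven <= spont.criterion_2sd:
            continue
        evoked = driven - spont.mean_rate_hz
        if (best is None or evoked > best[0]
                or (evoked == best[0] and stim.carrier_hz < best[1])):
            best = (evoked, stim.carrier_hz)
    return None if best is None else float(best[1])
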