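"""Core data model for amplitude-modulation (AM) tone experiments.

An experiment is described by a set of acoustic conditions
(:class:`StimulusSpec`) and, per recorded unit, the spike times of every
trial of every condition (:class:`TrialSpikes`, :class:`UnitRecording`).
Spike times are in milliseconds relative to stimulus onset; spikes in the
prestimulus window carry negative times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "StimulusKind",
    "StimulusSpec",
    "TrialSpikes",
    "UnitRecording",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a dataset violates the data-model invariants."""


class StimulusKind(str, Enum):
    PT = "PT"          # unmodulated pure tone
    AM = "AM"          # sinusoidally amplitude-modulated tone
    TUNING = "TUNING"  # short tones on a frequency x level grid


@dataclass(frozen=True)
class StimulusSpec:
    """One acoustic condition.

    Parameters
    ----------
    condition_id : str
        Unique identifier of the condition.
    kind : StimulusKind
        PT, AM or TUNING.
    carrier_hz : float
        Carrier (tone) frequency in Hz; must be > 0.
    mod_hz : float
        Modulation frequency in Hz; 0 for unmodulated stimuli.
    depth : float
        Modulation depth as a fraction in [0, 1] (AM protocol uses 1.0).
    level_db_spl : float
        Sound level in dB SPL.
    duration_ms : float
        Stimulus duration in ms (> 0).
    rise_fall_ms : float
        Cosine ramp duration in ms (>= 0).
    n_trials : int
        Number of stimulus repetitions (>= 1).
    prestim_ms : float
        Length of the recorded prestimulus window in ms (>= 0).
    """

    condition_id: str
    kind: StimulusKind
    carrier_hz: float
    mod_hz: float = 0.0
    depth: float = 0.0
    level_db_spl: float = 70.0
    duration_ms: float = 500.0
    rise_fall_ms: float = 5.0
    n_trials: int = 15
    prestim_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.carrier_hz <= 0:
            raise ValidationError(f"carrier_hz must be > 0, got {self.carrier_hz}")
        if self.mod_hz < 0:
            raise ValidationError(f"mod_hz must be >= 0, got {self.mod_hz}")
        if not 0.0 <= self.depth <= 1.0:
            raise ValidationError(f"depth must be in [0, 1], got {self.depth}")
        if self.duration_ms <= 0:
            raise ValidationError(f"duration_ms must be > 0, got {self.duration_ms}")
        if self.rise_fall_ms < 0:
            raise ValidationError("rise_fall_ms must be >= 0")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if self.prestim_ms < 0:
            raise ValidationError("prestim_ms must be >= 0")
        if self.kind == StimulusKind.AM and self.mod_hz == 0:
            raise ValidationError(
                f"AM condition {self.condition_id!r} must have mod_hz > 0"
            )
        if self.kind == StimulusKind.PT and self.mod_hz != 0:
            raise ValidationError(
                f"PT condition {self.condition_id!r} must have mod_hz = 0"
            )

    @property
    def period_ms(self) -> float:
        """Modulation period 1000 / f_m in ms (inf for unmodulated)."""
        return 1000.0 / self.mod_hz if self.mod_hz > 0 else float("inf")


@dataclass
class TrialSpikes:
    """Spike times of one trial, sorted ascending, in ms re stimulus onset."""

    unit_id: str
    condition_id: str
    trial_index: int
    spike_times_ms: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_ms, dtype=float)
        if t.ndim != 1:
            raise ValidationError("spike_times_ms must be one-dimensional")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValidationError(
                f"spike times of unit {self.unit_id!r}, condition "
                f"{self.condition_id!r}, trial {self.trial_index} are not sorted"
            )
        self.spike_times_ms = t

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_ms.size)


@dataclass
class UnitRecording:
    """All trials of one unit across conditions, with its group label.

    ``trials`` maps condition_id to the list of :class:`TrialSpikes`
    ordered by trial index.
    """

    unit_id: str
    group: str
    trials: dict[str, list[TrialSpikes]] = field(default_factory=dict)
    best_frequency_hz: Optional[float] = None

    def spikes(self, condition_id: str) -> list[np.ndarray]:
        """Per-trial spike-time arrays for one condition."""
        return [t.spike_times_ms for t in self.trials[condition_id]]

    def pooled_spikes(self, condition_id: str) -> np.ndarray:
        """All spike times of a condition pooled over trials (sorted)."""
        arrs = self.spikes(condition_id)
        if not arrs:
            return np.empty(0)
        return np.sort(np.concatenate(arrs))

    def n_trials(self, condition_id: str) -> int:
        return len(self.trials.get(condition_id, []))

    def validate_against(self, stimuli: dict[str, StimulusSpec]) -> None:
        """Check condition references, trial counts and spike-time ranges."""
        for cid, trials in self.trials.items():
            if cid not in stimuli:
                raise ValidationError(
                    f"unit {self.unit_id!r} references unknown condition {cid!r}"
                )
            stim = stimuli[cid]
            if len(trials) != stim.n_trials:
                raise ValidationError(
                    f"unit {self.unit_id!r}, condition {cid!r}: "
                    f"{len(trials)} trials found, {stim.n_trials} expected"
                )
            for tr in trials:
                t = tr.spike_times_ms
                if t.size and (t[0] < -stim.prestim_ms - 1e-9):
                    raise ValidationError(
                        f"unit {self.unit_id!r}, condition {cid!r}, trial "
                        f"{tr.trial_index}: spike at {t[0]:.3f} ms precedes the "
                        f"{stim.prestim_ms} ms prestimulus window"
                    )
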