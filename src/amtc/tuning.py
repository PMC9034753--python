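"""Tuning-curve metrics: characteristic frequency, threshold, Q40 sharpness.

A tuning curve is the mean driven rate on a frequency x level grid. The
characteristic frequency (CF) is the frequency whose lowest level evoking a
response above the spontaneous mean + 3 SD is minimal; that level is the
threshold. Q40 is the CF divided by the tuning-curve bandwidth measured
40 dB above the threshold at CF, with band edges refined by linear
interpolation in log2 frequency between the last sub-criterion and first
supra-criterion grid points (the 16-frequency grid spans six octaves, too
coarse for a raw-grid bandwidth).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import StimulusKind, StimulusSpec, UnitRecording
from .rates import SpontStats

__all__ = ["TuningCurve", "TuningMetrics", "tuning_curve_from_unit",
           "characteristic_frequency", "q40", "tuning_metrics"]


@dataclass
class TuningCurve:
    """Mean driven rates (spikes/s) on a complete frequency x level grid."""

    freqs_hz: np.ndarray          # ascending
    levels_db: np.ndarray         # ascending
    rates: np.ndarray             # shape (n_freqs, n_levels)
    spont: SpontStats

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, float)
        self.levels_db = np.asarray(self.levels_db, float)
        self.rates = np.asarray(self.rates, float)
        if self.rates.shape != (self.freqs_hz.size, self.levels_db.size):
            raise ValueError("rates grid does not match frequency/level axes")


@dataclass(frozen=True)
class TuningMetrics:
    cf_hz: Optional[float]
    threshold_db_spl: Optional[float]
    q40: Optional[float]


def tuning_curve_from_unit(
    unit: UnitRecording,
    stimuli: dict[str, StimulusSpec],
) -> TuningCurve:
    """Assemble the grid of mean during-stimulus rates from TUNING trials.

    The spontaneous baseline pools per-trial prestimulus rates over the
    whole grid (mean and SD across all tuning trials).
    """
    cells: dict[tuple[float, float], float] = {}
    pre_rates: list[float] = []
    for cid, trials in unit.trials.items():
        stim = stimuli[cid]
        if stim.kind != StimulusKind.TUNING:
            continue
        dur_s = stim.duration_ms * 1e-3
        counts = [
            np.count_nonzero((t.spike_times_ms >= 0)
                             & (t.spike_times_ms < stim.duration_ms))
            for t in trials
        ]
        cells[(stim.carrier_hz, stim.level_db_spl)] = float(np.mean(counts)) / dur_s
        if stim.prestim_ms > 0:
            w = stim.prestim_ms * 1e-3
            pre_rates += [
                np.count_nonzero((t.spike_times_ms >= -stim.prestim_ms)
                                 & (t.spike_times_ms < 0)) / w
                for t in trials
            ]
    if not cells:
        raise ValueError(f"unit {unit.unit_id!r} has no TUNING conditions")
    freqs = np.array(sorted({f for f, _ in cells}))
    levels = np.array(sorted({l for _, l in cells}))
    rates = np.empty((freqs.size, levels.size))
    for i, f in enumerate(freqs):
        for j, l in enumerate(levels):
            if (f, l) not in cells:
                raise ValueError(
                    f"tuning grid of unit {unit.unit_id!r} is incomplete at "
                    f"({f} Hz, {l} dB)"
                )
            rates[i, j] = cells[(f, l)]
    pre = np.asarray(pre_rates)
    spont = SpontStats(float(pre.mean()) if pre.size else 0.0,
                       float(pre.std(ddof=1)) if pre.size > 1 else 0.0)
    return TuningCurve(freqs, levels, rates, spont)


def characteristic_frequency(
    tc: TuningCurve,
) -> tuple[Optional[float], Optional[float]]:
    """CF and threshold: per frequency, the lowest level whose rate exceeds
    spont mean + 3 SD; CF is the frequency with the minimal such level.
    Ties break toward the higher rate at threshold, then the lower
    frequency. Returns (None, None) if no grid point passes."""
    crit = tc.spont.criterion_3sd
    best: tuple[float, float, float] | None = None  # (threshold, -rate, freq)
    for i, f in enumerate(tc.freqs_hz):
        passing = np.nonzero(tc.rates[i] > crit)[0]
        if passing.size == 0:
            continue
        j = passing[0]
        key = (float(tc.levels_db[j]), -float(tc.rates[i, j]), float(f))
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[2], best[0]


def _edge_log2(freqs: np.ndarray, rates: np.ndarray, crit: float,
               i_sub: int, i_sup: int) -> float:
    """Criterion crossing between two grid points, linear in log2(f)."""
    x0, x1 = np.log2(freqs[i_sub]), np.log2(freqs[i_sup])
    y0, y1 = rates[i_sub], rates[i_sup]
    if y1 == y0:
        return float(freqs[i_sup])
    frac = (crit - y0) / (y1 - y0)
    return float(2.0 ** (x0 + frac * (x1 - x0)))


def q40(
    tc: TuningCurve,
    cf_hz: float,
    threshold_db: float,
) -> Optional[float]:
    """Q40 = CF / bandwidth at threshold + 40 dB; None when not measurable.

    Undefined when the evaluation level exceeds the tested grid, when no
    frequency responds there, or when the response touches either frequency
    edge of the grid (bandwidth not bracketed).
    """
    level = threshold_db + 40.0
    if level > tc.levels_db.max() + 1e-9:
        return None
    j = int(np.argmin(np.abs(tc.levels_db - level)))
    if abs(tc.levels_db[j] - level) > 1e-6:
        return None
    crit = tc.spont.criterion_3sd
    col = tc.rates[:, j]
    resp = np.nonzero(col > crit)[0]
    if resp.size == 0:
        return None
    lo, hi = int(resp[0]), int(resp[-1])
    if lo == 0 or hi == tc.freqs_hz.size - 1:
        return None  # response reaches the grid edge
    f_low = _edge_log2(tc.freqs_hz, col, crit, lo - 1, lo)
    f_high = _edge_log2(tc.freqs_hz, col, crit, hi + 1, hi)
    bw = f_high - f_low
    if bw <= 0:
        return None
    return float(cf_hz / bw)


def tuning_metrics(tc: TuningCurve) -> TuningMetrics:
    cf, thr = characteristic_frequency(tc)
    if cf is None:
        return TuningMetrics(None, None, None)
    return TuningMetrics(cf, thr, q40(tc, cf, thr))
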