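"""Temporal-coding metrics for responses to sinusoidally AM tones.

Phase locking is quantified three ways:

* **Vector strength** of the pooled spike phases relative to the modulation
  cycle, with a Rayleigh test against circular uniformity.
* **NCCH** — a normalized cross-correlation histogram between one period of
  the 100%-depth sinusoidal envelope (the reference ``r[n]``, minimum at the
  period start) and the smoothed PSTH, locally normalized so every lag's
  value lies in [0, 1]. Because both signals are nonnegative, a flat
  response with nonzero rate still correlates positively (1/sqrt(1.5) for a
  perfectly flat PSTH).
* **PCH** — the offset-corrected (Pearson-like) variant: the reference is
  made zero-mean (``s[n]``) and the PSTH mean over the analysed window is
  subtracted, giving values in [-1, 1] and exactly 0 for a flat response.

Per period of the modulation, the within-period maximum of a histogram
yields a peak coefficient and a peak latency; the mean coefficient over the
M analysed periods is scaled by sqrt(M) to make coefficients comparable
across modulation frequencies (higher f_m => shorter reference relative to
the fixed 400-ms analysis window => smaller unscaled coefficients).

Peak latencies are reported as the position of the response maximum within
the stimulus period: the raw alignment lag of the correlation maximum plus
half a period (the reference peaks mid-period), unwrapped by whole periods
against the onset-response delay so that latencies up to about two periods
— as observed at high modulation frequencies — are representable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .psth import BIN_MS, PeriodSegmentation, SmoothedPSTH

__all__ = [
    "VectorStrengthResult",
    "ReferencePeriod",
    "CorrelationHistogram",
    "CorrelationResult",
    "vector_strength",
    "rayleigh_significant",
    "make_reference",
    "ncch",
    "pch",
    "per_period_peaks",
    "scaled_cc",
    "population_latency_stats",
    "latency_in_periods",
    "onset_delay",
    "unwrap_peak_latencies",
    "am_correlation_metrics",
]


# ---------------------------------------------------------------------------
# vector strength and Rayleigh test

@dataclass(frozen=True)
class VectorStrengthResult:
    """Resultant length of spike phases; ``vs`` is None when no spikes."""

    vs: Optional[float]
    n_spikes: int
    rayleigh_p: Optional[float]


def _rayleigh_p(n: int, vs: float) -> float:
    """Finite-n corrected Rayleigh p: exp(-Z) (1 + (2Z - Z^2) / 4n), Z = n vs^2."""
    z = n * vs * vs
    p = np.exp(-z) * (1.0 + (2.0 * z - z * z) / (4.0 * n))
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def vector_strength(
    spike_times_ms: np.ndarray,
    mod_hz: float,
    analysis_window: tuple[float, float],
) -> VectorStrengthResult:
    """Vector strength of spikes (pooled over trials/units) in the window.

    Phases are ``2 pi f_m t`` modulo one cycle; vs = |sum exp(i theta)| / n.
    """
    if mod_hz <= 0:
        raise ValueError("mod_hz must be > 0")
    t = np.asarray(spike_times_ms, dtype=float)
    t = t[(t >= analysis_window[0]) & (t < analysis_window[1])]
    n = int(t.size)
    if n == 0:
        return VectorStrengthResult(None, 0, None)
    theta = 2.0 * np.pi * mod_hz * t * 1e-3
    vs = float(np.abs(np.exp(1j * theta).mean()))
    return VectorStrengthResult(vs, n, _rayleigh_p(n, vs))


def rayleigh_significant(result: VectorStrengthResult, alpha: float = 0.01) -> bool:
    """True iff the Rayleigh test rejects circular uniformity at ``alpha``."""
    if result.n_spikes < 1 or result.rayleigh_p is None:
        raise ValueError("Rayleigh test requires at least one spike")
    return result.rayleigh_p < alpha


# ---------------------------------------------------------------------------
# reference period and correlation histograms

@dataclass(frozen=True)
class ReferencePeriod:
    """One period of the AM envelope on the 200-us grid.

    ``r`` is the nonnegative envelope (0 at the period start, 1 mid-period);
    ``s = r - mean(r)`` is its offset-corrected, zero-mean version.
    """

    mod_hz: float
    r: np.ndarray
    s: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.r.size)

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.mod_hz


def make_reference(mod_hz: float) -> ReferencePeriod:
    """Sample ``r[n] = (1 - cos(2 pi f_m t_n)) / 2`` over one period."""
    if mod_hz <= 0:
        raise ValueError("mod_hz must be > 0")
    n = int(round(1000.0 / mod_hz / BIN_MS))
    if n < 2:
        raise ValueError(
            f"modulation period of {mod_hz} Hz spans fewer than 2 bins"
        )
    phase = 2.0 * np.pi * np.arange(n) / n
    r = 0.5 * (1.0 - np.cos(phase))
    return ReferencePeriod(mod_hz, r, r - r.mean())


@dataclass
class CorrelationHistogram:
    """Correlation value per lag; ``lags_ms`` is the absolute time at which
    the reference window starts. ``degenerate`` marks an all-zero (NCCH) or
    zero-variance (PCH) input."""

    mod_hz: float
    lags_ms: np.ndarray
    values: np.ndarray
    kind: str  # "ncch" | "pch"
    degenerate: bool = False


def _sliding_energy(x: np.ndarray, n: int) -> np.ndarray:
    e = np.convolve(x * x, np.ones(n), mode="valid")
    return np.clip(e, 0.0, None)


def ncch(
    psth: SmoothedPSTH,
    reference: ReferencePeriod,
    analysis_window: tuple[float, float],
    normalization: str = "windowed",
) -> CorrelationHistogram:
    """Normalized cross-correlation histogram of PSTH vs envelope period.

    ``NCCH[k] = sum_n r[n] P[n+k] / sqrt(sum r^2 * sum_n P[n+k]^2)`` with
    both sums over the N reference samples at each lag (the default
    ``"windowed"`` normalization), so values lie in [0, 1]; lags with zero
    PSTH energy map to 0. ``normalization="global"`` instead divides by the
    PSTH energy of one *average* period of the whole analysed window at
    every lag — a constant denominator for comparison; its values are not
    bounded by 1 lag-by-lag.
    """
    if normalization not in ("windowed", "global"):
        raise ValueError(f"unknown normalization {normalization!r}")
    p = psth.window(*analysis_window)
    n = reference.n_samples
    if p.size < n:
        raise ValueError("analysis window shorter than one reference period")
    num = np.correlate(p, reference.r, mode="valid")
    if normalization == "windowed":
        energy = _sliding_energy(p, n)
    else:
        energy = np.full(num.size, float(np.sum(p * p)) * n / p.size)
    den = np.sqrt(float(np.sum(reference.r**2)) * energy)
    values = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    if normalization == "windowed":
        values = np.clip(values, 0.0, 1.0)
    lag0 = psth.t0_ms + max(psth.index_of(analysis_window[0]), 0) * psth.bin_width_ms
    lags = lag0 + np.arange(values.size) * psth.bin_width_ms
    return CorrelationHistogram(reference.mod_hz, lags, values, "ncch",
                                degenerate=not np.any(p))


def pch(
    psth: SmoothedPSTH,
    reference: ReferencePeriod,
    analysis_window: tuple[float, float],
) -> CorrelationHistogram:
    """Offset-corrected (Pearson-like) correlation histogram.

    The zero-mean reference ``s[n]`` is correlated with the PSTH after
    subtracting its mean over the analysed window; values lie in [-1, 1] and
    zero-variance windows map to 0.
    """
    p = psth.window(*analysis_window)
    n = reference.n_samples
    if p.size < n:
        raise ValueError("analysis window shorter than one reference period")
    pc = p - p.mean() if p.size else p
    num = np.correlate(pc, reference.s, mode="valid")
    den = np.sqrt(float(np.sum(reference.s**2)) * _sliding_energy(pc, n))
    values = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    values = np.clip(values, -1.0, 1.0)
    lag0 = psth.t0_ms + max(psth.index_of(analysis_window[0]), 0) * psth.bin_width_ms
    lags = lag0 + np.arange(values.size) * psth.bin_width_ms
    return CorrelationHistogram(reference.mod_hz, lags, values, "pch",
                                degenerate=bool(np.ptp(pc) == 0 if pc.size else True))


def per_period_peaks(
    corr_hist: CorrelationHistogram,
    segmentation: PeriodSegmentation,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-period maxima of a correlation histogram.

    For each segmented period, the peak is the maximum histogram value over
    the lags falling inside that period (ties -> earliest lag); the raw
    latency is the peak lag minus the start of the *stimulus* cycle
    containing the period (the nearest multiple of the modulation period).
    Periods containing no lag are skipped.
    """
    period = segmentation.nominal_period_ms
    bin_ms = float(np.median(np.diff(corr_hist.lags_ms))) if \
        corr_hist.lags_ms.size > 1 else period
    lats, coeffs = [], []
    for a, b in segmentation.periods():
        # a period is measurable only when its whole lag range exists in
        # the histogram (the last window periods lose their tail lags)
        if b > corr_hist.lags_ms[-1] + 1.5 * bin_ms:
            continue
        mask = (corr_hist.lags_ms >= a) & (corr_hist.lags_ms < b)
        if not np.any(mask):
            continue
        idx = np.nonzero(mask)[0]
        j = idx[int(np.argmax(corr_hist.values[idx]))]
        nominal_start = np.round(a / period) * period
        lats.append(corr_hist.lags_ms[j] - nominal_start)
        coeffs.append(corr_hist.values[j])
    return np.asarray(lats), np.asarray(coeffs)


def scaled_cc(coefficients: Sequence[float]) -> float:
    """Mean per-period coefficient scaled by sqrt(M), M = number of periods."""
    c = np.asarray(coefficients, dtype=float)
    if c.size == 0:
        raise ValueError("scaled_cc requires at least one period coefficient")
    return float(c.mean() * np.sqrt(c.size))


def population_latency_stats(
    latencies_ms: Sequence[float],
) -> tuple[float, Optional[float]]:
    """Mean and sample SD (jitter); SD is None for a single value."""
    x = np.asarray(latencies_ms, dtype=float)
    if x.size < 1:
        raise ValueError("latency statistics require at least one value")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else None
    return float(x.mean()), sd


def latency_in_periods(latency_ms: float, mod_hz: float) -> float:
    """Latency expressed in multiples of the modulation period."""
    if mod_hz <= 0:
        raise ValueError("mod_hz must be > 0")
    return latency_ms * mod_hz / 1000.0


# ---------------------------------------------------------------------------
# peak-position latencies (stimulus-referenced, up to ~2 periods)

def onset_delay(psth: SmoothedPSTH, mod_hz: float) -> Optional[float]:
    """Delay of the first response bump after stimulus onset.

    Within the first ~2.5 modulation periods, the earliest crossing of 60%
    of the trace's local range is climbed to its local maximum. Using the
    first bump (rather than the global maximum) keeps the estimate anchored
    to the stimulus cycle that generated it even when onset adaptation is
    weak and later bumps fluctuate above the first. None if flat.
    """
    period = 1000.0 / mod_hz
    seg = psth.window(0.0, min(2.5 * period, psth.t1_ms))
    if seg.size == 0 or np.ptp(seg) <= 0:
        return None
    thr = seg.min() + 0.6 * np.ptp(seg)
    idx = int(np.argmax(seg >= thr))
    while idx + 1 < seg.size and seg[idx + 1] > seg[idx]:
        idx += 1
    i0 = max(psth.index_of(0.0), 0)
    return float((i0 + idx) * psth.bin_width_ms + psth.t0_ms)


def unwrap_peak_latencies(
    raw_latencies_ms: np.ndarray,
    mod_hz: float,
    onset_delay_ms: Optional[float] = None,
) -> np.ndarray:
    """Convert raw alignment lags into response-peak positions.

    The reference envelope peaks half a period after its start, so the
    correlation maximum at raw lag ``l`` corresponds to a response maximum
    at ``l + T/2`` (modulo the period T). Each period's position is chosen
    among ``(l mod T) + T/2 + j T`` as the candidate closest to the onset
    delay (or to the cohort median when no onset estimate exists), allowing
    latencies up to about two periods.
    """
    period = 1000.0 / mod_hz
    wrapped = np.mod(raw_latencies_ms, period) + period / 2.0
    if onset_delay_ms is None:
        onset_delay_ms = float(np.median(wrapped))
    j = np.round((onset_delay_ms - wrapped) / period)
    return wrapped + j * period


# ---------------------------------------------------------------------------
# condition-level driver

@dataclass
class CorrelationResult:
    """Correlation-derived temporal metrics for one modulation frequency."""

    mod_hz: float
    per_period_peak_latency_ms: np.ndarray
    per_period_peak_coeff: np.ndarray
    cc_nc: float
    cc_pc: float
    peak_latency_ms: Optional[float]
    jitter_ms: Optional[float]
    n_periods: int
    degenerate: bool = False


def am_correlation_metrics(
    smoothed_psth: SmoothedPSTH,
    segmentation: PeriodSegmentation,
    analysis_window: tuple[float, float],
) -> CorrelationResult:
    """NCCH/PCH metrics of one smoothed PSTH for one AM condition.

    Peak latencies and per-period coefficients are taken from the NCCH
    (CC_NC); CC_PC is the sqrt(M)-scaled mean of the per-period PCH peak
    coefficients.
    """
    mod_hz = segmentation.mod_hz
    ref = make_reference(mod_hz)
    h_nc = ncch(smoothed_psth, ref, analysis_window)
    h_pc = pch(smoothed_psth, ref, analysis_window)
    raw_lats, nc_coeffs = per_period_peaks(h_nc, segmentation)
    _, pc_coeffs = per_period_peaks(h_pc, segmentation)
    if raw_lats.size == 0:
        return CorrelationResult(mod_hz, raw_lats, nc_coeffs,
                                 float("nan"), float("nan"), None, None, 0,
                                 degenerate=True)
    d = onset_delay(smoothed_psth, mod_hz)
    positions = unwrap_peak_latencies(raw_lats, mod_hz, d)
    mean_lat, jitter = population_latency_stats(positions)
    return CorrelationResult(
        mod_hz=mod_hz,
        per_period_peak_latency_ms=positions,
        per_period_peak_coeff=nc_coeffs,
        cc_nc=scaled_cc(nc_coeffs),
        cc_pc=scaled_cc(pc_coeffs),
        peak_latency_ms=mean_lat,
        jitter_ms=jitter,
        n_periods=int(raw_lats.size),
        degenerate=h_nc.degenerate or h_pc.degenerate,
    )
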