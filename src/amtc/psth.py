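"""PSTH construction, Gaussian smoothing and period segmentation.

Spike times are binned at a fixed 200-us resolution into a trial-averaged
peristimulus time histogram (PSTH, spikes/s). For an AM condition the PSTH
is smoothed with a Gaussian kernel whose standard deviation depends on the
modulation frequency,

    sigma(f_m) = 80 / f_m  [ms],

so that slow modulations are smoothed broadly and fast ones retain
temporal resolution. Per-unit smoothed PSTHs superposed (summed) over units
form the convolved population PSTH (CPSTH); its local minima around each
nominal period boundary k / f_m define the start and end of the response
periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .datamodel import TrialSpikes

__all__ = [
    "BIN_MS",
    "SmoothedPSTH",
    "PeriodSegmentation",
    "bin_psth",
    "kernel_sigma",
    "convolve",
    "population_cpsth",
    "segment_periods",
]

BIN_MS = 0.2  # fixed 200-us bin width


@dataclass
class SmoothedPSTH:
    """Binned (and optionally Gaussian-smoothed) firing-rate trace.

    ``values`` holds the per-bin rate in spikes/s averaged over trials and,
    for a population trace, summed over ``n_units`` units. ``sigma_ms`` is
    the kernel SD used, or None for a raw histogram.
    """

    t0_ms: float
    values: np.ndarray
    n_trials: int
    n_units: int = 1
    sigma_ms: Optional[float] = None
    bin_width_ms: float = BIN_MS

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def t1_ms(self) -> float:
        return self.t0_ms + self.n_bins * self.bin_width_ms

    def bin_starts(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_bins) * self.bin_width_ms

    def index_of(self, t_ms: float) -> int:
        """Index of the bin containing time ``t_ms`` (left-closed bins)."""
        return int(np.floor((t_ms - self.t0_ms) / self.bin_width_ms + 1e-9))

    def window(self, t_start_ms: float, t_stop_ms: float) -> np.ndarray:
        """Values of bins whose start lies in [t_start_ms, t_stop_ms)."""
        i0 = max(self.index_of(t_start_ms), 0)
        i1 = min(self.index_of(t_stop_ms), self.n_bins)
        return self.values[i0:i1]


@dataclass
class PeriodSegmentation:
    """Period boundaries for one modulation frequency.

    ``boundaries_ms`` is the ascending list of period start/end times
    (length = number of periods + 1); ``fallback`` marks a degenerate CPSTH
    for which the nominal grid was used.
    """

    mod_hz: float
    boundaries_ms: np.ndarray
    fallback: bool = False

    @property
    def nominal_period_ms(self) -> float:
        return 1000.0 / self.mod_hz

    @property
    def n_periods(self) -> int:
        return int(self.boundaries_ms.size) - 1

    def periods(self) -> Iterable[tuple[float, float]]:
        b = self.boundaries_ms
        return zip(b[:-1], b[1:])


def bin_psth(
    trials: Sequence[TrialSpikes] | Sequence[np.ndarray],
    window: tuple[float, float],
) -> SmoothedPSTH:
    """Bin spike trains into a raw trial-averaged PSTH at 200-us resolution.

    Bin ``b`` counts spikes with ``t`` in ``[t0 + 0.2 b, t0 + 0.2 (b+1))``
    (left-closed) and is scaled to spikes/s by ``1 / (n_trials * 0.0002 s)``.
    """
    if len(trials) == 0:
        raise ValueError("bin_psth requires at least one trial")
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty binning window")
    n_bins = int(np.ceil((t1 - t0) / BIN_MS - 1e-9))
    counts = np.zeros(n_bins)
    for tr in trials:
        t = tr.spike_times_ms if isinstance(tr, TrialSpikes) else np.asarray(tr, float)
        if t.size == 0:
            continue
        idx = np.floor((t - t0) / BIN_MS + 1e-9).astype(int)
        keep = (idx >= 0) & (idx < n_bins)
        np.add.at(counts, idx[keep], 1.0)
    rate = counts / (len(trials) * BIN_MS * 1e-3)
    return SmoothedPSTH(t0_ms=t0, values=rate, n_trials=len(trials))


def kernel_sigma(mod_hz: float) -> float:
    """Kernel SD in ms for modulation frequency ``mod_hz``: sigma = 80 / f_m."""
    if mod_hz <= 0:
        raise ValueError(f"mod_hz must be > 0, got {mod_hz}")
    return 80.0 / mod_hz


def convolve(psth: SmoothedPSTH, sigma_ms: float) -> SmoothedPSTH:
    """Smooth a PSTH with a unit-area Gaussian kernel of SD ``sigma_ms``.

    The kernel is truncated at +-4 sigma and renormalized on the discrete
    grid; boundaries are handled by symmetric reflection, which conserves
    total area. The output lives on the same bin grid.
    """
    if sigma_ms <= 0:
        raise ValueError(f"sigma_ms must be > 0, got {sigma_ms}")
    if sigma_ms < psth.bin_width_ms / 2:
        warnings.warn(
            f"kernel sigma {sigma_ms} ms is below half the bin width; "
            "the discrete kernel is renormalized but poorly resolved",
            stacklevel=2,
        )
    sigma_bins = sigma_ms / psth.bin_width_ms
    smoothed = gaussian_filter1d(psth.values, sigma_bins, mode="reflect",
                                 truncate=4.0)
    return replace(psth, values=smoothed, sigma_ms=sigma_ms)


def population_cpsth(
    psths: Sequence[SmoothedPSTH],
    sigma_ms: float,
    average: bool = False,
) -> SmoothedPSTH:
    """Superpose per-unit raw PSTHs into the convolved population PSTH.

    Each unit's raw PSTH is smoothed with ``sigma_ms`` and the results are
    summed across units (set ``average=True`` for a per-unit mean, useful
    when comparing populations of unequal size).
    """
    if len(psths) == 0:
        raise ValueError("population_cpsth requires at least one unit PSTH")
    first = psths[0]
    for p in psths[1:]:
        if p.n_bins != first.n_bins or p.t0_ms != first.t0_ms:
            raise ValueError("unit PSTHs must share one bin grid")
    total = np.zeros(first.n_bins)
    for p in psths:
        total += convolve(p, sigma_ms).values
    if average:
        total /= len(psths)
    return SmoothedPSTH(
        t0_ms=first.t0_ms,
        values=total,
        n_trials=first.n_trials,
        n_units=len(psths),
        sigma_ms=sigma_ms,
    )


def segment_periods(
    cpsth: SmoothedPSTH,
    mod_hz: float,
    analysis_window: tuple[float, float],
) -> PeriodSegmentation:
    """Place period boundaries at CPSTH minima near the nominal grid.

    For every nominal boundary ``k / f_m`` inside the analysis window the
    boundary is moved to the minimum of the CPSTH within +-25% of one period
    around the nominal position (ties resolved toward the earliest bin). A
    flat CPSTH yields the nominal grid with ``fallback=True``.
    """
    if mod_hz <= 0:
        raise ValueError("mod_hz must be > 0")
    t_start, t_stop = analysis_window
    period = 1000.0 / mod_hz
    k0 = int(np.ceil(t_start / period - 1e-9))
    k1 = int(np.floor(t_stop / period + 1e-9))
    if k1 - k0 < 1:
        raise ValueError("analysis window shorter than one modulation period")
    nominal = np.arange(k0, k1 + 1) * period

    region = cpsth.window(t_start, t_stop)
    flat = region.size == 0 or np.ptp(region) <= 1e-12 * max(np.abs(region).max(), 1.0)
    if flat:
        return PeriodSegmentation(mod_hz, nominal, fallback=True)

    bounds = np.empty_like(nominal)
    for i, t_nom in enumerate(nominal):
        lo = max(t_nom - 0.25 * period, cpsth.t0_ms)
        hi = min(t_nom + 0.25 * period, cpsth.t1_ms - cpsth.bin_width_ms)
        i0 = cpsth.index_of(lo)
        i1 = cpsth.index_of(hi)
        seg = cpsth.values[i0:i1 + 1]
        j = int(np.argmin(seg))  # argmin takes the earliest minimum on ties
        bounds[i] = cpsth.t0_ms + (i0 + j) * cpsth.bin_width_ms
    # enforce strictly increasing boundaries
    for i in range(1, bounds.size):
        if bounds[i] <= bounds[i - 1]:
            bounds[i] = bounds[i - 1] + cpsth.bin_width_ms
    return PeriodSegmentation(mod_hz, bounds, fallback=False)
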