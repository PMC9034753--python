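"""Full analysis pipeline over a dataset, with group comparisons.

Per unit and AM condition the pipeline computes spontaneous statistics,
first-spike latency, vector strength with Rayleigh test, and per-unit
correlation metrics. Per group and modulation frequency it builds the
convolved population PSTH (CPSTH), segments it into periods, and derives
the population's evoked rate per period, vector strength, peak latency and
jitter, and the scaled correlation coefficients CC_NC and CC_PC. Groups are
compared metric-by-metric with the two-tailed Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datamodel import StimulusKind, StimulusSpec, UnitRecording
from .psth import (SmoothedPSTH, bin_psth, convolve, kernel_sigma,
                   population_cpsth, segment_periods)
from .rates import (SpontStats, best_frequency, evoked_rate_per_period,
                    first_spike_latency, population_fsl, spontaneous_stats)
from .temporal import (am_correlation_metrics, latency_in_periods,
                       rayleigh_significant, vector_strength)
from .tuning import tuning_curve_from_unit, tuning_metrics

__all__ = [
    "PipelineConfig",
    "GroupComparison",
    "PipelineResult",
    "select_units",
    "run_pipeline",
    "compare_groups",
    "fold_change",
]


@dataclass
class PipelineConfig:
    """Tunable analysis parameters (defaults follow the study protocol)."""

    analysis_onset_exclusion_ms: float = 100.0
    prestim_ms: float = 500.0
    fm_ladder: tuple[float, ...] = tuple(float(f) for f in range(10, 170, 10))
    require_fc_equals_bf: bool = True
    carrier_offset_octaves: float = 0.0
    octave_tolerance: float = 1e-3
    alpha_rayleigh: float = 0.01
    alpha_group: float = 0.05
    bonferroni: bool = False
    population_average: bool = False  # CPSTH: sum (default) or per-unit mean
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(open(path)) or {}
        if "fm_ladder" in doc:
            doc["fm_ladder"] = tuple(float(f) for f in doc["fm_ladder"])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["fm_ladder"] = list(self.fm_ladder)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mod_hz: Optional[float]
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    u_statistic: float
    p_two_tailed: float


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric: str = "",
    mod_hz: Optional[float] = None,
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-tailed Mann-Whitney U test.

    Exact null distribution (full enumeration) when min(n, m) <= 8 and the
    pooled sample has no ties; normal approximation with tie correction and
    continuity correction otherwise.
    """
    a = np.asarray([v for v in values_a if not np.isnan(v)], float)
    b = np.asarray([v for v in values_b if not np.isnan(v)], float)
    if a.size == 0 or b.size == 0:
        raise ValueError("compare_groups requires two nonempty samples")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        metric=metric, mod_hz=mod_hz, group_a=group_a, group_b=group_b,
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        n_a=int(a.size), n_b=int(b.size),
        u_statistic=float(res.statistic), p_two_tailed=float(min(res.pvalue, 1.0)),
    )


def fold_change(median_a: float, median_b: float) -> float:
    """Ratio of two medians, reported to 2 decimals."""
    if median_b <= 0:
        raise ValueError("fold change requires a positive denominator")
    return round(median_a / median_b, 2)


def select_units(
    units: Mapping[str, UnitRecording],
    stimuli: Mapping[str, StimulusSpec],
    config: PipelineConfig,
    log: Optional[list[str]] = None,
) -> dict[str, list[str]]:
    """Map each kept unit to its AM conditions, applying the carrier rule.

    With ``require_fc_equals_bf`` a unit's AM condition is analysed only
    when its carrier sits at ``carrier_offset_octaves`` (default 0, i.e.
    carrier = best frequency) from the unit's BF. Raises when nothing
    survives; every rejection is logged.
    """
    log = log if log is not None else []
    kept: dict[str, list[str]] = {}
    for uid, rec in units.items():
        conds: list[str] = []
        for cid in rec.trials:
            stim = stimuli[cid]
            if stim.kind != StimulusKind.AM or stim.mod_hz not in config.fm_ladder:
                continue
            if config.require_fc_equals_bf:
                if rec.best_frequency_hz is None:
                    log.append(f"unit {uid}: no best frequency; AM conditions skipped")
                    break
                offset = abs(np.log2(stim.carrier_hz / rec.best_frequency_hz))
                if abs(offset - abs(config.carrier_offset_octaves)) > config.octave_tolerance:
                    log.append(
                        f"unit {uid}, condition {cid}: carrier "
                        f"{stim.carrier_hz:.0f} Hz is {offset:.3f} oct from BF; dropped"
                    )
                    continue
            conds.append(cid)
        if conds:
            kept[uid] = sorted(conds)
        else:
            log.append(f"unit {uid}: no qualifying AM conditions")
    if not kept:
        raise ValueError(
            "unit selection left no units; reasons: " + "; ".join(log[-10:])
        )
    return kept


@dataclass
class PipelineResult:
    unit_metrics: pd.DataFrame
    population_metrics: pd.DataFrame
    evoked_rates: pd.DataFrame
    tuning: pd.DataFrame
    comparisons: pd.DataFrame
    log: list[str] = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "unit_metrics": self.unit_metrics,
            "population_metrics": self.population_metrics,
            "evoked_rates": self.evoked_rates,
            "tuning_metrics": self.tuning,
            "group_comparisons": self.comparisons,
        }


def _unit_condition_metrics(rec, stim, spont, config):
    window = (config.analysis_onset_exclusion_ms, stim.duration_ms)
    sigma = kernel_sigma(stim.mod_hz)
    raw = bin_psth(rec.spikes(stim.condition_id), (-stim.prestim_ms, stim.duration_ms))
    smooth = convolve(raw, sigma)
    seg = segment_periods(smooth, stim.mod_hz, window)
    corr = am_correlation_metrics(smooth, seg, window)
    vs = vector_strength(rec.pooled_spikes(stim.condition_id), stim.mod_hz, window)
    fsl = first_spike_latency(rec, stim, spont)
    return raw, seg, corr, vs, fsl


def run_pipeline(
    units: Mapping[str, UnitRecording],
    stimuli: Mapping[str, StimulusSpec],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the complete analysis; deterministic given inputs and config."""
    config = config or PipelineConfig()
    log: list[str] = []

    pt_stimuli = sorted(
        (s for s in stimuli.values() if s.kind == StimulusKind.PT),
        key=lambda s: s.carrier_hz,
    )
    have_tuning = any(s.kind == StimulusKind.TUNING for s in stimuli.values())

    # --- best frequencies -------------------------------------------------
    for uid, rec in units.items():
        if rec.best_frequency_hz is None and pt_stimuli:
            pt_with_trials = [s for s in pt_stimuli if s.condition_id in rec.trials]
            if pt_with_trials:
                spont_pt = spontaneous_stats(rec, pt_with_trials[0])
                rec.best_frequency_hz = best_frequency(rec, pt_with_trials, spont_pt)
                if rec.best_frequency_hz is None:
                    log.append(f"unit {uid}: best frequency undefined")

    selection = select_units(units, stimuli, config, log)

    # --- per-unit metrics -------------------------------------------------
    unit_rows = []
    per_group: dict[tuple[str, float], list[tuple[str, object, object]]] = {}
    for uid in sorted(selection):
        rec = units[uid]
        for cid in sorted(selection[uid]):
            stim = stimuli[cid]
            spont = spontaneous_stats(rec, stim)
            raw, seg, corr, vs, fsl = _unit_condition_metrics(rec, stim, spont, config)
            if seg.fallback:
                log.append(f"unit {uid}, condition {cid}: flat CPSTH, nominal grid used")
            if corr.degenerate:
                log.append(f"unit {uid}, condition {cid}: degenerate correlation window")
            sig = (rayleigh_significant(vs, config.alpha_rayleigh)
                   if vs.n_spikes > 0 else False)
            unit_rows.append({
                "unit_id": uid, "group": rec.group, "condition_id": cid,
                "mod_hz": stim.mod_hz,
                "bf_hz": rec.best_frequency_hz,
                "spont_mean_hz": spont.mean_rate_hz,
                "spont_sd_hz": spont.sd_rate_hz,
                "fsl_ms": np.nan if fsl is None else fsl,
                "vs": np.nan if vs.vs is None else vs.vs,
                "rayleigh_p": np.nan if vs.rayleigh_p is None else vs.rayleigh_p,
                "rayleigh_significant": sig,
                "n_spikes": vs.n_spikes,
                "peak_latency_ms": (np.nan if corr.peak_latency_ms is None
                                    else corr.peak_latency_ms),
                "jitter_ms": np.nan if corr.jitter_ms is None else corr.jitter_ms,
                "cc_nc": corr.cc_nc, "cc_pc": corr.cc_pc,
                "mean_evoked_rate_hz": float(np.mean(
                    evoked_rate_per_period(raw, seg, spont))),
            })
            per_group.setdefault((rec.group, stim.mod_hz), []).append((uid, rec, stim))
    unit_df = pd.DataFrame(unit_rows)

    # --- population metrics per group and f_m -----------------------------
    pop_rows, evoked_rows = [], []
    for (grp, fm) in sorted(per_group):
        members = per_group[(grp, fm)]
        window = (config.analysis_onset_exclusion_ms, members[0][2].duration_ms)
        sigma = kernel_sigma(fm)
        raws = [bin_psth(rec.spikes(stim.condition_id),
                         (-stim.prestim_ms, stim.duration_ms))
                for _, rec, stim in members]
        cpsth = population_cpsth(raws, sigma, average=config.population_average)
        seg = segment_periods(cpsth, fm, window)
        if seg.fallback:
            log.append(f"group {grp}, f_m {fm}: flat population CPSTH")
        corr = am_correlation_metrics(cpsth, seg, window)

        pre_rates = []
        pooled = []
        for _, rec, stim in members:
            w = stim.prestim_ms * 1e-3
            pre_rates += [
                np.count_nonzero((t >= -stim.prestim_ms) & (t < 0)) / w
                for t in rec.spikes(stim.condition_id)
            ]
            pooled.append(rec.pooled_spikes(stim.condition_id))
        pre = np.asarray(pre_rates)
        pop_spont = SpontStats(float(pre.mean()),
                               float(pre.std(ddof=1)) if pre.size > 1 else 0.0)
        # evoked rate uses the unsmoothed population PSTH (per-unit mean)
        acc = np.zeros_like(raws[0].values)
        for r in raws:
            acc += r.values
        mean_raw = SmoothedPSTH(t0_ms=raws[0].t0_ms, values=acc / len(raws),
                                n_trials=raws[0].n_trials, n_units=len(raws))
        evoked = evoked_rate_per_period(mean_raw, seg, pop_spont)
        for p, r in enumerate(evoked):
            evoked_rows.append({"group": grp, "mod_hz": fm, "period_index": p,
                                "evoked_rate_hz": r})

        vs = vector_strength(np.concatenate(pooled), fm, window)
        sub = unit_df[(unit_df.group == grp) & (unit_df.mod_hz == fm)]
        fsl_values = list(sub.fsl_ms)
        try:
            fsl_med, n_undef = population_fsl(fsl_values)
        except ValueError:
            fsl_med, n_undef = np.nan, len(fsl_values)
            log.append(f"group {grp}, f_m {fm}: no defined unit FSL")
        lat = corr.peak_latency_ms
        pop_rows.append({
            "group": grp, "mod_hz": fm, "n_units": len(members),
            "spont_mean_hz": pop_spont.mean_rate_hz,
            "spont_median_hz": float(sub.spont_mean_hz.median()),
            "fsl_median_ms": fsl_med, "n_fsl_undefined": n_undef,
            "vs": np.nan if vs.vs is None else vs.vs,
            "rayleigh_p": np.nan if vs.rayleigh_p is None else vs.rayleigh_p,
            "peak_latency_ms": np.nan if lat is None else lat,
            "peak_latency_periods": (np.nan if lat is None
                                     else latency_in_periods(lat, fm)),
            "jitter_ms": np.nan if corr.jitter_ms is None else corr.jitter_ms,
            "mean_peak_latency_ms": float(sub.peak_latency_ms.mean()),
            "sd_peak_latency_over_units_ms": float(sub.peak_latency_ms.std(ddof=1))
                if len(sub) > 1 else np.nan,
            "cc_nc": corr.cc_nc, "cc_pc": corr.cc_pc,
            "mean_evoked_rate_hz": float(evoked.mean()),
            "segmentation_fallback": seg.fallback,
        })
    pop_df = pd.DataFrame(pop_rows)

    # --- tuning metrics ---------------------------------------------------
    tuning_rows = []
    if have_tuning:
        for uid in sorted(units):
            rec = units[uid]
            if not any(stimuli[c].kind == StimulusKind.TUNING for c in rec.trials):
                continue
            tc = tuning_curve_from_unit(rec, dict(stimuli))
            tm = tuning_metrics(tc)
            if tm.cf_hz is None:
                log.append(f"unit {uid}: characteristic frequency undefined")
            tuning_rows.append({
                "unit_id": uid, "group": rec.group,
                "cf_hz": np.nan if tm.cf_hz is None else tm.cf_hz,
                "threshold_db_spl": (np.nan if tm.threshold_db_spl is None
                                     else tm.threshold_db_spl),
                "q40": np.nan if tm.q40 is None else tm.q40,
            })
    tuning_df = pd.DataFrame(
        tuning_rows, columns=["unit_id", "group", "cf_hz", "threshold_db_spl", "q40"]
    )

    # --- group comparisons ------------------------------------------------
    comp_rows = []
    groups = sorted(unit_df.group.unique()) if len(unit_df) else []
    if len(groups) == 2:
        ga, gb = groups
        metrics = ["spont_mean_hz", "fsl_ms", "vs", "peak_latency_ms",
                   "cc_nc", "cc_pc", "mean_evoked_rate_hz"]
        for fm in sorted(unit_df.mod_hz.unique()):
            for m in metrics:
                va = unit_df[(unit_df.group == ga) & (unit_df.mod_hz == fm)][m].dropna()
                vb = unit_df[(unit_df.group == gb) & (unit_df.mod_hz == fm)][m].dropna()
                if len(va) == 0 or len(vb) == 0:
                    continue
                comp = compare_groups(va, vb, metric=m, mod_hz=fm,
                                      group_a=ga, group_b=gb)
                comp_rows.append(vars(comp) | {
                    "significant": comp.p_two_tailed < (
                        config.alpha_group / (len(metrics) * len(config.fm_ladder))
                        if config.bonferroni else config.alpha_group)
                })
    comp_df = pd.DataFrame(comp_rows)
    return PipelineResult(unit_df, pop_df, pd.DataFrame(evoked_rows),
                          tuning_df, comp_df, log)
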