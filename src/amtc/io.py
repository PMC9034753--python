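"""Reading and writing of spike tables, stimulus metadata and result tables.

Formats
-------
spikes.csv
    Delimited text with header ``unit_id,group,condition_id,trial_index,
    spike_time_ms`` — one row per spike. Units without spikes may still be
    declared through the ``units`` manifest of the metadata document.
stimuli.json / stimuli.yaml
    Structured document with a ``stimuli`` list (one mapping per condition,
    fields of :class:`~amtc.datamodel.StimulusSpec`) and an optional
    ``units`` manifest (``unit_id``, ``group``, optional
    ``best_frequency_hz``).
results/*.tsv
    Tab-separated tables, one per metric family; dimensionless quantities
    formatted to 4 decimals, millisecond quantities to 2.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datamodel import StimulusKind, StimulusSpec, TrialSpikes, UnitRecording, ValidationError

__all__ = ["load_dataset", "write_dataset", "load_stimuli", "write_results"]

SPIKE_COLUMNS = ["unit_id", "group", "condition_id", "trial_index", "spike_time_ms"]


def load_stimuli(path: str | os.PathLike) -> tuple[dict[str, StimulusSpec], list[dict]]:
    """Load the stimulus-metadata document (JSON or YAML).

    Returns the condition map and the (possibly empty) units manifest.
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "stimuli" not in doc:
        raise ValidationError(f"{path}: expected a mapping with a 'stimuli' list")
    stimuli: dict[str, StimulusSpec] = {}
    for entry in doc["stimuli"]:
        entry = dict(entry)
        entry["kind"] = StimulusKind(entry["kind"])
        spec = StimulusSpec(**entry)
        if spec.condition_id in stimuli:
            raise ValidationError(f"duplicate condition_id {spec.condition_id!r}")
        stimuli[spec.condition_id] = spec
    return stimuli, list(doc.get("units", []))


def load_dataset(
    spike_table_path: str | os.PathLike,
    stimulus_meta_path: str | os.PathLike,
) -> tuple[dict[str, UnitRecording], dict[str, StimulusSpec]]:
    """Load and validate a spike table plus its stimulus metadata.

    Every declared (unit, condition) pair yields ``n_trials`` trials, empty
    trials included. Spike times are never reordered; out-of-order or
    duplicated rows raise :class:`ValidationError` naming the offending row.
    """
    stimuli, manifest = load_stimuli(stimulus_meta_path)
    table = pd.read_csv(spike_table_path)
    missing = [c for c in SPIKE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(
            f"{spike_table_path}: missing column(s) {', '.join(missing)}"
        )

    units: dict[str, UnitRecording] = {}
    groups: dict[str, str] = {}
    bf: dict[str, float | None] = {}
    for entry in manifest:
        uid = str(entry["unit_id"])
        groups[uid] = str(entry.get("group", ""))
        bf[uid] = entry.get("best_frequency_hz")

    spikes: dict[tuple[str, str, int], list[float]] = {}
    for row in table.itertuples(index=True):
        uid = str(row.unit_id)
        cid = str(row.condition_id)
        if cid not in stimuli:
            raise ValidationError(
                f"row {row.Index}: unknown condition_id {cid!r}"
            )
        grp = str(row.group)
        if groups.setdefault(uid, grp) != grp:
            raise ValidationError(
                f"row {row.Index}: unit {uid!r} appears with group {grp!r} "
                f"and {groups[uid]!r}"
            )
        key = (uid, cid, int(row.trial_index))
        bucket = spikes.setdefault(key, [])
        t = float(row.spike_time_ms)
        if bucket:
            if t < bucket[-1]:
                raise ValidationError(
                    f"row {row.Index}: spike times of unit {uid!r}, condition "
                    f"{cid!r}, trial {key[2]} are not sorted ascending"
                )
            if t == bucket[-1]:
                raise ValidationError(
                    f"row {row.Index}: duplicate spike (unit {uid!r}, condition "
                    f"{cid!r}, trial {key[2]}, t={t} ms)"
                )
        bucket.append(t)

    unit_conditions: dict[str, set[str]] = {}
    for (uid, cid, _idx) in spikes:
        unit_conditions.setdefault(uid, set()).add(cid)
    # units declared in the manifest participate in every condition
    for entry in manifest:
        uid = str(entry["unit_id"])
        conds = entry.get("condition_ids", list(stimuli))
        unit_conditions.setdefault(uid, set()).update(map(str, conds))

    for uid in sorted(unit_conditions):
        rec = UnitRecording(unit_id=uid, group=groups.get(uid, ""),
                            best_frequency_hz=bf.get(uid))
        for cid in sorted(unit_conditions[uid]):
            stim = stimuli[cid]
            rec.trials[cid] = [
                TrialSpikes(uid, cid, k,
                            np.asarray(spikes.get((uid, cid, k), []), dtype=float))
                for k in range(stim.n_trials)
            ]
        rec.validate_against(stimuli)
        units[uid] = rec
    return units, stimuli


def write_dataset(
    units: Mapping[str, UnitRecording],
    stimuli: Mapping[str, StimulusSpec],
    out_dir: str | os.PathLike,
) -> tuple[Path, Path]:
    """Write ``spikes.csv`` and ``stimuli.json``; inverse of :func:`load_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    manifest = []
    for uid in sorted(units):
        rec = units[uid]
        entry = {"unit_id": uid, "group": rec.group,
                 "condition_ids": sorted(rec.trials)}
        if rec.best_frequency_hz is not None:
            entry["best_frequency_hz"] = rec.best_frequency_hz
        manifest.append(entry)
        for cid in sorted(rec.trials):
            for tr in rec.trials[cid]:
                for t in tr.spike_times_ms:
                    rows.append((uid, rec.group, cid, tr.trial_index, t))
    spike_path = out / "spikes.csv"
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(
        spike_path, index=False, float_format="%.6f"
    )
    doc = {
        "stimuli": [
            {**{k: (v.value if isinstance(v, StimulusKind) else v)
                for k, v in vars(s).items()}}
            for s in (stimuli[c] for c in sorted(stimuli))
        ],
        "units": manifest,
    }
    meta_path = out / "stimuli.json"
    meta_path.write_text(json.dumps(doc, indent=1))
    return spike_path, meta_path


def _format_value(col: str, x) -> str:
    if pd.isna(x):
        return ""
    if isinstance(x, (int, np.integer)) or col.endswith(("_id", "_index", "n", "_n")):
        return str(x)
    if col.endswith("_ms"):
        return f"{float(x):.2f}"
    if isinstance(x, (float, np.floating)):
        return f"{float(x):.4f}"
    return str(x)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Write one TSV per metric family.

    Millisecond columns (``*_ms``) are written with 2 decimals, other float
    columns with 4; empty tables produce header-only files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        formatted = df.copy()
        for col in formatted.columns:
            formatted[col] = [
                _format_value(col, x) for x in formatted[col]
            ]
        formatted.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
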