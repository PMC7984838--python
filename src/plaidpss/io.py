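"""File formats: trial-table CSV, stimulus-set config, result records."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stimuli import StimulusCondition, StimulusSet

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "write_results",
    "stimulus_set_to_yaml",
    "stimulus_set_from_yaml",
]

TRIAL_COLUMNS = [
    "animal_id",
    "neuron_id",
    "trial",
    "kind",
    "pattern_direction_deg",
    "dori_deg",
    "contrast",
    "count",
    "window_s",
]

_KINDS = {"grating", "plaid", "blank"}


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Errors name the offending rows (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        raise ValueError(f"trial table has unknown columns: {extra}")
    if df.empty:
        return df.astype({"count": int}, errors="ignore")
    bad_kind = df.index[~df["kind"].isin(_KINDS)]
    if len(bad_kind):
        raise ValueError(f"unknown stimulus kind at rows {[i + 1 for i in bad_kind[:10]]}")
    counts = df["count"].to_numpy()
    bad_count = df.index[(counts < 0) | (counts != np.floor(counts))]
    if len(bad_count):
        raise ValueError(
            f"negative or non-integer counts at rows {[i + 1 for i in bad_count[:10]]}"
        )
    bad_window = df.index[df["window_s"] <= 0]
    if len(bad_window):
        raise ValueError(f"nonpositive window_s at rows {[i + 1 for i in bad_window[:10]]}")
    return df.astype({"count": int, "trial": int})


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (round-trips exactly through read_trials)."""
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def write_results(records, path) -> None:
    """Write per-neuron result records to CSV or JSON by file extension."""
    path = Path(path)
    if hasattr(records, "to_dict") and not isinstance(records, pd.DataFrame):
        records = [records.to_dict()]
    elif not isinstance(records, pd.DataFrame):
        records = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in records]
    if path.suffix == ".json":
        data = records.to_dict(orient="records") if isinstance(records, pd.DataFrame) else records
        path.write_text(json.dumps(data, indent=2, default=float) + "\n")
    else:
        df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
        df.to_csv(path, index=False)


def stimulus_set_to_yaml(stim_set: StimulusSet, path) -> None:
    """Serialise a stimulus set to a structured text config."""
    contrasts = sorted({c.contrast for c in stim_set.conditions if c.kind != "blank"})
    doc = {
        "paradigm": stim_set.paradigm,
        "directions": [float(d) for d in stim_set.directions],
        "dori_values": [float(d) for d in stim_set.dori_values],
        "reps": int(stim_set.reps),
        "window_s": float(stim_set.window_s),
        "contrasts": [float(c) for c in contrasts],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def stimulus_set_from_yaml(path) -> StimulusSet:
    """Rebuild a stimulus set from its config file."""
    doc = yaml.safe_load(Path(path).read_text())
    directions = np.asarray(doc["directions"], dtype=float)
    dori_values = np.asarray(doc["dori_values"], dtype=float)
    contrast = float(doc["contrasts"][0]) if doc.get("contrasts") else 1.0
    conds: list[StimulusCondition] = []
    for d in directions:
        conds.append(StimulusCondition("grating", float(d), 0.0, contrast))
    for dori in dori_values:
        for d in directions:
            conds.append(StimulusCondition("plaid", float(d), float(dori), contrast))
    conds.append(StimulusCondition("blank", 0.0, 0.0, 0.0))
    return StimulusSet(
        conditions=tuple(conds),
        paradigm=doc["paradigm"],
        reps=int(doc["reps"]),
        window_s=float(doc["window_s"]),
        directions=directions,
        dori_values=dori_values,
    )
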