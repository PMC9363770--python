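"""TrialSet persistence (TSV matrix + JSON sidecar) and an MNE adapter.

The on-disk format is deliberately plain: one tab-separated matrix per
trial collection (rows = trials, columns = samples) next to a JSON sidecar
holding the sampling rate, onset index, per-trial labels and any generator
or filter metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .trialset import TrialSet


def save_trialset(ts: TrialSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` and ``<prefix>.json``; returns the two paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".tsv")
    js = prefix.with_suffix(".json")
    np.savetxt(tsv, ts.data, delimiter="\t", fmt="%.8g")
    sidecar = {
        "fs": ts.fs,
        "onset_index": int(ts.onset_index),
        "n_trials": ts.n_trials,
        "n_samples": ts.n_samples,
        "conditions": ts.conditions.tolist(),
        "participant_ids": ts.participant_ids.tolist(),
        "good_flags": ts.good_flags.tolist(),
        "meta": _jsonable(ts.meta),
    }
    js.write_text(json.dumps(sidecar, indent=1))
    return tsv, js


def load_trialset(prefix: str | Path) -> TrialSet:
    prefix = Path(prefix)
    data = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    side = json.loads(prefix.with_suffix(".json").read_text())
    return TrialSet(
        data=data,
        fs=side["fs"],
        onset_index=side["onset_index"],
        conditions=np.array(side["conditions"]),
        participant_ids=np.array(side["participant_ids"]),
        good_flags=np.array(side["good_flags"], dtype=bool),
        meta=side.get("meta", {}),
    )


def from_mne_raw(
    raw,
    channel: str | int = 0,
    pre: float = 1.0,
    post: float = 5.0,
    condition_map: dict[str, str] | None = None,
) -> TrialSet:
    """Segment a single channel of an MNE Raw object into a TrialSet.

    Onsets come from the Raw's annotations; each annotation description is
    mapped to a condition label through ``condition_map`` (identity when
    omitted).  Works with any Raw subclass, e.g. ``mne.io.read_raw_edf`` for
    EDF recordings or an in-memory ``RawArray``.
    """
    from .preprocess import segment  # local import: avoids a cycle

    picks = [channel] if isinstance(channel, int) else [raw.ch_names.index(channel)]
    data = raw.get_data(picks=picks)[0] * 1e6  # MNE uses volts; we use microvolts
    fs = float(raw.info["sfreq"])
    onsets = np.round(np.asarray(raw.annotations.onset) * fs).astype(int)
    labels = np.asarray(raw.annotations.description)
    if condition_map:
        labels = np.array([condition_map.get(d, d) for d in labels])
    return segment(data, fs, onsets, pre=pre, post=post, conditions=labels)


def read_edf_trials(path: str | Path, **kwargs) -> TrialSet:
    """Read an EDF recording and segment it on its annotations."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return from_mne_raw(raw, **kwargs)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
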