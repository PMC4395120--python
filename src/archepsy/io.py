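"""On-disk layout: session manifest, channel tables, tidy result tables.

A simulated cohort is persisted as

* ``manifest.json`` — subjects, classes, epoch boundaries, sampling
  rates, channel file paths, seed and config hash;
* one two-column CSV (``time_s,value``) per channel per epoch under
  ``signals/<subject>/<class>/<baseline|stimulus>_<channel>.csv``;
* ``sam.csv`` — one row per stimulus: subject, class, arousal, valence,
  dominance.

Feature matrices, CV results and comparison tables are plain CSV with
header rows; readers round-trip what the writers emit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CHANNELS,
    ChannelSignal,
    Epoch,
    EpochPair,
    SAMReport,
    SessionRecording,
)


def write_cohort(
    sessions: list[SessionRecording],
    out_dir: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
    persist_signals: bool = True,
) -> Path:
    """Persist a cohort; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "config_hash": config_hash,
        "channels": list(CHANNELS),
        "subjects": [],
    }
    sam_rows = []
    for session in sessions:
        entry = {"subject_id": session.subject_id, "classes": {}}
        for cls, pair in session.epochs.items():
            sam_rows.append(
                (session.subject_id, cls, pair.sam.arousal, pair.sam.valence,
                 pair.sam.dominance)
            )
            cls_entry: dict = {"epochs": {}}
            for tag, epoch in (("baseline", pair.baseline), ("stimulus", pair.stimulus)):
                files = {}
                for ch in CHANNELS:
                    sig = epoch[ch]
                    rel = f"signals/{session.subject_id}/{cls}/{tag}_{ch}.csv"
                    if persist_signals:
                        path = out / rel
                        path.parent.mkdir(parents=True, exist_ok=True)
                        arr = np.column_stack([sig.times, sig.values])
                        np.savetxt(
                            path, arr, fmt="%.6f", delimiter=",",
                            header="time_s,value", comments="",
                        )
                    files[ch] = {
                        "path": rel,
                        "sampling_rate": sig.sampling_rate,
                        "start_time": sig.start_time,
                        "n_samples": len(sig.values),
                    }
                cls_entry["epochs"][tag] = files
            entry["classes"][cls] = cls_entry
        manifest["subjects"].append(entry)

    sam = pd.DataFrame(
        sam_rows, columns=["subject", "class", "arousal", "valence", "dominance"]
    )
    sam.to_csv(out / "sam.csv", index=False)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_cohort(manifest_path: str | Path) -> list[SessionRecording]:
    """Load a persisted cohort back into memory (signals required)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    sam = pd.read_csv(root / "sam.csv").set_index(["subject", "class"])

    sessions = []
    for entry in manifest["subjects"]:
        session = SessionRecording(subject_id=entry["subject_id"])
        for cls, cls_entry in entry["classes"].items():
            epochs = {}
            for tag, files in cls_entry["epochs"].items():
                signals = {}
                for ch, meta in files.items():
                    tab = pd.read_csv(root / meta["path"])
                    signals[ch] = ChannelSignal(
                        ch, meta["sampling_rate"], tab["value"].to_numpy(),
                        meta["start_time"],
                    )
                epochs[tag] = Epoch(signals)
            row = sam.loc[(entry["subject_id"], cls)]
            session.epochs[cls] = EpochPair(
                baseline=epochs["baseline"],
                stimulus=epochs["stimulus"],
                sam=SAMReport(
                    int(row["arousal"]), int(row["valence"]), int(row["dominance"])
                ),
            )
        sessions.append(session)
    return sessions


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Feature matrix CSV: subject and class columns plus the canonical
    feature names as header."""
    matrix.reset_index().to_csv(path, index=False, float_format="%.10g")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.set_index(["subject", "class"])
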