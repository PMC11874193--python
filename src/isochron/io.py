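"""File interchange: events tables, parameter manifests, EDF input.

Events travel as tab-separated text with columns ``sequence_id``,
``position``, ``onset_s``, ``is_deviant`` (plus ``onset_abs_s`` when
absolute recording-time onsets are known); manifests of generative
parameters are plain CSV.  Real raw EEG is read from EDF through MNE's
native reader.  No EDF writer is provided: recordings produced by the
generator live in memory or, via :func:`recording_to_mne`, in any
format MNE exports.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Recording

__all__ = ["write_events", "read_events", "write_manifest", "read_manifest",
           "read_edf", "recording_to_mne"]


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event table as TSV using the interchange schema."""
    out = pd.DataFrame({
        "sequence_id": events["sequence_id"],
        "position": events["position"],
        "onset_s": events["onset"],
        "is_deviant": events["is_deviant"].astype(int),
    })
    if "onset_abs" in events.columns:
        out["onset_abs_s"] = events["onset_abs"]
    out.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a TSV event table back into the internal column layout."""
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame({
        "sequence_id": df["sequence_id"].astype(int),
        "position": df["position"].astype(int),
        "onset": df["onset_s"].astype(float),
        "is_deviant": df["is_deviant"].astype(bool),
    })
    if "onset_abs_s" in df.columns:
        out["onset_abs"] = df["onset_abs_s"].astype(float)
    return out


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_edf(path: str | Path, subject_id: str = "", group: str = "") -> Recording:
    """Load a raw EDF recording into a :class:`Recording` (volts -> uV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                     list(raw.ch_names), subject_id=subject_id, group=group)


def recording_to_mne(recording: Recording):
    """Wrap a :class:`Recording` as an ``mne.io.RawArray`` (uV -> volts)."""
    import mne

    info = mne.create_info(list(recording.channel_labels), recording.fs,
                           ch_types="eeg", verbose="error")
    return mne.io.RawArray(recording.data * 1e-6, info, verbose="error")
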