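"""Portable trial-tensor container (HDF5) and the optional GDF adapter.

Layout of the container::

    /data            float64, channels x samples x trials (microvolts)
    /labels          UTF-8 strings, one per trial
    /artifact_flags  bool, one per trial
    /montage         UTF-8 strings, one per channel
    attrs: fs, session_id, time_zero

The same layout (minus artifact flags, plus the ``window`` attribute)
stores preprocessed epochs. Writing then reading is bit-identical for
data and metadata.
"""

from __future__ import annotations

import h5py
import numpy as np

from .preprocess import EpochSet, TrialSet

_STR = h5py.string_dtype(encoding="utf-8")


def write_trial_set(path, trial_set: TrialSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trial_set.data)
        f.create_dataset("labels", data=np.asarray(trial_set.labels, dtype=object), dtype=_STR)
        f.create_dataset("artifact_flags", data=trial_set.artifact_flags)
        f.create_dataset("montage", data=np.asarray(trial_set.montage, dtype=object), dtype=_STR)
        f.attrs["fs"] = trial_set.fs
        f.attrs["session_id"] = trial_set.session_id
        f.attrs["time_zero"] = trial_set.time_zero
        f.attrs["kind"] = "trials"


def read_trial_set(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        return TrialSet(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            montage=[s.decode() if isinstance(s, bytes) else s for s in f["montage"][()]],
            labels=np.array(
                [s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]]
            ),
            artifact_flags=f["artifact_flags"][()].astype(bool),
            session_id=str(f.attrs["session_id"]),
            time_zero=float(f.attrs["time_zero"]),
        )


def write_epoch_set(path, epoch_set: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epoch_set.data)
        f.create_dataset("labels", data=np.asarray(epoch_set.labels, dtype=object), dtype=_STR)
        f.create_dataset("montage", data=np.asarray(epoch_set.montage, dtype=object), dtype=_STR)
        f.attrs["fs"] = epoch_set.fs
        f.attrs["session_id"] = epoch_set.session_id
        f.attrs["window"] = list(epoch_set.window)
        f.attrs["kind"] = "epochs"


def read_epoch_set(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            montage=[s.decode() if isinstance(s, bytes) else s for s in f["montage"][()]],
            labels=np.array(
                [s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]]
            ),
            window=tuple(f.attrs["window"]),
            session_id=str(f.attrs["session_id"]),
        )


def read_gdf(path, session_id: str = "S1") -> TrialSet:
    """Optional adapter: read a GDF competition recording into a TrialSet.

    Requires the optional ``mne`` dependency (``pip install mibci[gdf]``).
    Cue onsets (event codes 769-772) define trials of 7.5 s starting 2 s
    before the cue, matching the paradigm clock used throughout this
    package. Artifact-marked trials (code 1023) are flagged, not removed.

    This adapter is provided for working with the real competition
    recordings and is not exercised by the test suite.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading GDF files requires the optional 'mne' extra") from exc

    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    eeg = raw.copy().pick("eeg")
    fs = float(eeg.info["sfreq"])
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    cue_codes = {"769": "LH", "770": "RH", "771": "F", "772": "T"}
    code_lut = {
        v: cue_codes[k] for k, v in event_id.items() if k in cue_codes
    }
    artifact_code = event_id.get("1023")

    data = eeg.get_data() * 1e6  # volts -> microvolts
    pre, post = 2.0, 5.5  # cue at t=2 s on the trial clock; 7.5 s total
    n_pre, n_post = int(round(pre * fs)), int(round(post * fs))
    trials, labels, flags = [], [], []
    artifact_samples = set(
        events[events[:, 2] == artifact_code, 0].tolist()
    ) if artifact_code is not None else set()
    for sample, _, code in events:
        if code not in code_lut:
            continue
        start = sample - n_pre
        if start < 0 or sample + n_post > data.shape[1]:
            continue
        trials.append(data[:, start : sample + n_post])
        labels.append(code_lut[code])
        flags.append(any(abs(sample - a) < n_pre for a in artifact_samples))
    return TrialSet(
        data=np.stack(trials, axis=-1),
        fs=fs,
        montage=list(eeg.ch_names),
        labels=np.array(labels),
        artifact_flags=np.array(flags, dtype=bool),
        session_id=session_id,
        time_zero=0.0,
    )
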