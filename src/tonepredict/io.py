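"""Plain-text / raw-binary persistence for the pipeline's containers.

Epochs live in a directory holding ``metadata.json`` plus ``data.bin``
(float32, little-endian, C-order, [trial][channel][time]).  Everything else is
TSV or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decoding import TimeGenMatrix
from .sequences import ToneSequence, TransitionMatrix
from .simulate import Audiogram, EpochsContainer, SubjectSpec


def save_epochs(epochs: EpochsContainer, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": epochs.subject_id,
        "sfreq": epochs.sfreq,
        "tmin": float(epochs.times_s[0]),
        "n_trials": int(epochs.n_trials),
        "n_channels": int(epochs.n_channels),
        "n_times": int(len(epochs.times_s)),
        "channel_names": [f"MEG{i:04d}" for i in range(epochs.n_channels)],
        "condition": [str(c) for c in epochs.condition],
        "tone_id": [int(x) for x in epochs.labels],
        "is_omission": [bool(x) for x in epochs.is_omission],
    }
    (out / "metadata.json").write_text(json.dumps(meta))
    epochs.data.astype("<f4").tofile(out / "data.bin")
    return out


def load_epochs(in_dir) -> EpochsContainer:
    src = Path(in_dir)
    meta = json.loads((src / "metadata.json").read_text())
    shape = (meta["n_trials"], meta["n_channels"], meta["n_times"])
    data = np.fromfile(src / "data.bin", dtype="<f4").reshape(shape)
    times = meta["tmin"] + np.arange(meta["n_times"]) / meta["sfreq"]
    return EpochsContainer(
        data=data,
        times_s=times,
        labels=np.asarray(meta["tone_id"], dtype=np.int64),
        condition=np.asarray(meta["condition"], dtype=object),
        sfreq=meta["sfreq"],
        subject_id=meta["subject_id"],
        is_omission=np.asarray(meta["is_omission"], dtype=bool),
    )


def save_events_tsv(seq: ToneSequence, path, carrier_freqs_hz=None) -> None:
    seq.to_frame(carrier_freqs_hz).to_csv(path, sep="\t", index=False)


def save_transition_matrix_tsv(m: TransitionMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t")


def save_timegen(tg: TimeGenMatrix, path_prefix) -> None:
    """Long-format TSV (train_time_s, test_time_s, accuracy) plus JSON sidecar."""
    prefix = Path(path_prefix)
    tr, te = np.meshgrid(tg.train_times_s, tg.test_times_s, indexing="ij")
    pd.DataFrame(
        {"train_time_s": tr.ravel(), "test_time_s": te.ravel(), "accuracy": tg.acc.ravel()}
    ).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    sidecar = {
        "subject_id": tg.subject_id,
        "test_condition": tg.test_condition,
        "n_train_times": len(tg.train_times_s),
        "n_test_times": len(tg.test_times_s),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def load_timegen(path_prefix) -> TimeGenMatrix:
    prefix = Path(path_prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    train = np.unique(df["train_time_s"])
    test = np.unique(df["test_time_s"])
    acc = df["accuracy"].to_numpy().reshape(len(train), len(test))
    return TimeGenMatrix(
        acc=acc,
        train_times_s=train,
        test_times_s=test,
        test_condition=sidecar["test_condition"],
        subject_id=sidecar["subject_id"],
    )


def save_cohort_manifest(cohort_specs, epoch_paths, path) -> None:
    """JSON manifest: one entry per subject with group, audiogram, distress, path."""
    subjects = []
    for spec, ep_path in zip(cohort_specs, epoch_paths):
        subjects.append(
            {
                "subject_id": spec.subject_id,
                "group": spec.group,
                "alpha_pre": spec.alpha_pre,
                "snr": spec.snr,
                "audiogram": {
                    "freqs_hz": list(spec.audiogram.freqs_hz),
                    "left_db": [float(x) for x in spec.audiogram.left_db],
                    "right_db": [float(x) for x in spec.audiogram.right_db],
                },
                "distress": spec.distress,
                "epochs_path": str(ep_path),
            }
        )
    Path(path).write_text(json.dumps({"subjects": subjects}, indent=1))


def load_cohort_manifest(path) -> list[tuple[SubjectSpec, Path]]:
    entries = json.loads(Path(path).read_text())["subjects"]
    out = []
    for e in entries:
        spec = SubjectSpec(
            subject_id=e["subject_id"],
            group=e["group"],
            alpha_pre=e["alpha_pre"],
            snr=e["snr"],
            audiogram=Audiogram(
                freqs_hz=tuple(e["audiogram"]["freqs_hz"]),
                left_db=np.asarray(e["audiogram"]["left_db"]),
                right_db=np.asarray(e["audiogram"]["right_db"]),
            ),
            distress=e["distress"],
        )
        out.append((spec, Path(e["epochs_path"])))
    return out
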