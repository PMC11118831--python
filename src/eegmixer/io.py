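"""Reading and writing recordings, epoch archives, and model checkpoints.

Supported recording formats:

* **EDF** — read through :mod:`mne` (``pip install eegmixer[edf]``).
* **CSV** — one row per channel; the first field of each row is the channel
  label, the remaining fields are samples in microvolts.  Sampling rate,
  subject ID, and label travel in a JSON sidecar ``<file>.json`` with keys
  ``fs``, ``subject_id``, ``label`` (sidecar values can be overridden by
  keyword arguments).
* **HDF5** — dataset ``/data`` of shape [channels x samples] with root
  attributes ``fs``, ``subject_id``, ``label``, ``channel_names``.

Epoch archives are HDF5 files with datasets ``/epochs`` [E x C x S],
``/labels``, ``/subject_ids`` and root attributes ``fs``, ``epoch_seconds``,
``channel_names``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError
from .preprocess import EpochSet, Recording


# --------------------------------------------------------------- recordings
def read_recording(path: str | Path, format: str | None = None, *,
                   subject_id: str | None = None, label: int | None = None,
                   fs: float | None = None) -> Recording:
    """Read a recording, inferring the format from the suffix if not given."""
    path = Path(path)
    if format is None:
        format = {".edf": "edf", ".csv": "csv", ".h5": "hdf5", ".hdf5": "hdf5"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise FormatError(f"cannot infer format from suffix of {path.name!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        return _read_edf(path, subject_id=subject_id, label=label)
    if format == "csv":
        return _read_csv(path, subject_id=subject_id, label=label, fs=fs)
    if format == "hdf5":
        return _read_hdf5(path, subject_id=subject_id, label=label)
    raise FormatError(f"unknown recording format {format!r}")


def _read_edf(path: Path, *, subject_id: str | None, label: int | None) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise FormatError("reading EDF requires the optional mne dependency") from exc
    _check_edf_uniform_rate(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; recordings are in microvolts
    return Recording(
        subject_id=subject_id or path.stem,
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        label=label,
    )


def _check_edf_uniform_rate(path: Path) -> None:
    """Reject EDFs whose signals carry different sampling rates.

    mne silently resamples mixed-rate EDFs; a montage recording with
    per-channel rates is malformed for this pipeline, so peek at the
    samples-per-record header field before handing the file over.
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path.name}: truncated EDF header")
        try:
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path.name}: malformed EDF header") from exc
        # per-signal header: label(16) transducer(80) dim(8) phys min/max(8+8)
        # dig min/max(8+8) prefilter(80) precede the 8-byte samples-per-record
        sig_header = fh.read(ns * 256)
    offset = ns * 216
    counts = set()
    for i in range(ns):
        label_field = sig_header[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
        if label_field == "EDF Annotations":
            continue
        counts.add(sig_header[offset + 8 * i : offset + 8 * (i + 1)].decode("ascii").strip())
    if len(counts) > 1:
        raise FormatError(f"{path.name}: channels disagree on sampling rate")


def _read_csv(path: Path, *, subject_id: str | None, label: int | None,
              fs: float | None) -> Recording:
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fs = fs if fs is not None else meta.get("fs")
    if fs is None:
        raise FormatError(f"{path.name}: sampling rate missing (no sidecar, no --fs)")
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            names.append(row[0].strip())
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: non-numeric sample") from exc
    if not rows:
        raise FormatError(f"{path.name}: empty file")
    if len({len(r) for r in rows}) != 1:
        raise FormatError(f"{path.name}: rows have unequal sample counts")
    return Recording(
        subject_id=subject_id or meta.get("subject_id", path.stem),
        data=np.asarray(rows),
        fs=float(fs),
        channel_names=names,
        label=label if label is not None else meta.get("label"),
    )


def _as_str(value) -> str:
    return value.decode() if isinstance(value, bytes) else str(value)


def _read_hdf5(path: Path, *, subject_id: str | None, label: int | None) -> Recording:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FormatError(f"{path.name}: missing /data dataset")
        data = f["data"][()]
        attrs = dict(f.attrs)
    if "fs" not in attrs:
        raise FormatError(f"{path.name}: missing fs attribute")
    raw_label = attrs.get("label", None)
    if raw_label is not None and int(raw_label) < 0:
        raw_label = None
    names = [_as_str(n) for n in attrs["channel_names"]]
    return Recording(
        subject_id=subject_id or str(attrs.get("subject_id", path.stem)),
        data=data,
        fs=float(attrs["fs"]),
        channel_names=names,
        label=label if label is not None else (None if raw_label is None else int(raw_label)),
    )


def write_recording_hdf5(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = rec.fs
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["label"] = -1 if rec.label is None else int(rec.label)
        f.attrs["channel_names"] = [n.encode() for n in rec.channel_names]


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for name, row in zip(rec.channel_names, rec.data):
            writer.writerow([name] + [repr(float(v)) for v in row])
    sidecar = {"fs": rec.fs, "subject_id": rec.subject_id, "label": rec.label}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


# ------------------------------------------------------------ epoch archive
def write_epochs(es: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=es.epochs)
        f.create_dataset("labels", data=es.labels.astype(np.int64))
        f.create_dataset(
            "subject_ids", data=np.asarray([str(s).encode() for s in es.subject_ids])
        )
        f.attrs["fs"] = es.fs
        f.attrs["epoch_seconds"] = es.epoch_seconds
        f.attrs["channel_names"] = [n.encode() for n in es.channel_names]


def read_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            epochs=f["epochs"][()],
            labels=f["labels"][()],
            subject_ids=np.asarray([_as_str(s) for s in f["subject_ids"][()]], dtype=object),
            fs=float(f.attrs["fs"]),
            epoch_seconds=float(f.attrs["epoch_seconds"]),
            channel_names=[_as_str(n) for n in f.attrs["channel_names"]],
        )


# --------------------------------------------------------------- checkpoints
CHECKPOINT_SCHEMA = 1


def save_checkpoint(path: str | Path, config_dict: dict, params: dict) -> None:
    """Write a model checkpoint: config as JSON, parameters as named arrays."""
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = CHECKPOINT_SCHEMA
        f.attrs["config"] = json.dumps(config_dict)
        g = f.create_group("params")
        for name, value in params.items():
            arr = value.data if hasattr(value, "data") else np.asarray(value)
            g.create_dataset(name, data=arr)


def load_checkpoint(path: str | Path) -> tuple[dict, dict]:
    """Read back ``(config_dict, {name: ndarray})``."""
    with h5py.File(path, "r") as f:
        if int(f.attrs.get("schema", -1)) != CHECKPOINT_SCHEMA:
            raise FormatError(f"unsupported checkpoint schema in {path}")
        config = json.loads(f.attrs["config"])
        params = {name: ds[()] for name, ds in f["params"].items()}
    return config, params
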