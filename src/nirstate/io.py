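"""File formats, pipeline configuration, and the end-to-end session runner.

One normative TSV dialect throughout: tab-separated, '.' decimal, header
row, UTF-8, LF.  Recordings carry their metadata in '#'-prefixed header
lines; events live in a sibling TSV.  A minimal SNIRF (HDF5) writer and
reader are provided for cross-format checks.

Every :func:`run_session` call emits a :class:`RunManifest` capturing
the configuration, seeds, input digests and per-stage record counts —
enough to re-run bit-identically and to keep any dropped data visible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import CvResult, SubjectResult, crossvalidate, replay_online
from .features import FeatureMatrix, build_basis, extract_features
from .mbll import (
    HemoSeries,
    OpticalRecording,
    OpticsConstants,
    default_constants,
    intensity_to_od,
    od_to_hemoglobin,
)
from .montage import MontageSpec, default_montage
from .preprocess import preprocess

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_hemo",
    "read_hemo",
    "write_features",
    "read_features",
    "write_snirf",
    "read_snirf",
    "run_session",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage parameter, with the study's stated values as defaults."""

    baseline_window: tuple[float, float] = (0.0, 5.0)
    epoch_offset: float = 2.0
    epoch_duration: float = 8.0
    filter_order: int = 6
    filter_cutoff: float = 0.6
    filter_stage: str = "continuous"  # or "epoch"
    basis_sigma: float = 1.0
    basis_spacing: float = 1.0
    chromophore: str = "both"  # hbo | hbr | both
    svm_c: float = 1.0
    cv_folds: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: dict
    package_version: str
    input_digest: str
    session: str
    n_samples: int = 0
    n_channels_long: int = 0
    n_epochs: int = 0
    n_epochs_dropped: int = 0
    class_counts: dict = field(default_factory=dict)
    fold_assignment: list = field(default_factory=list)
    accuracy_pct: float | None = None
    outputs: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


# -- recording TSV ------------------------------------------------------------


def write_recording(rec: OpticalRecording, path, events_path=None) -> None:
    path = Path(path)
    cols = [
        f"{cid}_{wl:g}"
        for cid in rec.channel_ids
        for wl in rec.wavelengths_nm
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# nirstate recording v1\n")
        fh.write(f"# sampling_rate_hz\t{rec.sampling_rate:g}\n")
        fh.write("# wavelengths_nm\t%g,%g\n" % tuple(rec.wavelengths_nm))
        fh.write("# channels\t%s\n" % ",".join(rec.channel_ids))
        fh.write("time_s\t" + "\t".join(cols) + "\n")
        flat = rec.intensity.reshape(rec.n_samples, -1)
        for t, row in zip(rec.time, flat):
            fh.write("%.6f\t" % t + "\t".join("%.10g" % v for v in row) + "\n")
    if events_path is None:
        events_path = path.with_name(path.stem + "_events.tsv")
    write_events(rec.events, events_path)


def read_recording(path, events_path=None, montage: MontageSpec | None = None) -> OpticalRecording:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    for ln in path.read_text(encoding="utf-8").splitlines():
        if ln.startswith("#"):
            parts = ln[1:].strip().split("\t")
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
            continue
        if header is None:
            header = ln.split("\t")
            continue
        rows.append(ln.split("\t"))
    for key in ("sampling_rate_hz", "wavelengths_nm", "channels"):
        if key not in meta:
            raise ValueError(f"malformed recording header: missing {key}")
    channel_ids = tuple(meta["channels"].split(","))
    wavelengths = tuple(float(x) for x in meta["wavelengths_nm"].split(","))
    data = np.array([[float(v) for v in r] for r in rows])
    time = data[:, 0]
    intensity = data[:, 1:].reshape(len(rows), len(channel_ids), len(wavelengths))
    neg = np.argwhere(intensity <= 0)
    if neg.size:
        s, c, _ = neg[0]
        raise ValueError(
            f"non-positive intensity in {path.name} at row {s + 1}, "
            f"channel {channel_ids[c]}"
        )
    if events_path is None:
        candidate = path.with_name(path.stem + "_events.tsv")
        events = read_events(candidate) if candidate.exists() else []
    else:
        events = read_events(events_path)
    return OpticalRecording(
        time=time,
        intensity=intensity,
        channel_ids=channel_ids,
        wavelengths_nm=wavelengths,  # type: ignore[arg-type]
        sampling_rate=float(meta["sampling_rate_hz"]),
        events=events,
        montage=montage,
    )


def write_events(events, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("onset_s\tduration_s\tlabel\n")
        for onset, dur, label in events:
            fh.write(f"{onset:g}\t{dur:g}\t{label}\n")


def read_events(path) -> list[tuple[float, float, str]]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != ["onset_s", "duration_s", "label"]:
        raise ValueError(f"malformed events file {path}")
    out = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        onset, dur, label = ln.split("\t")
        out.append((float(onset), float(dur), label))
    return out


# -- hemoglobin TSV -----------------------------------------------------------


def write_hemo(series: HemoSeries, path, events_path=None) -> None:
    path = Path(path)
    cols = [f"{cid}_{ch}" for cid in series.channel_ids for ch in ("hbo", "hbr")]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# nirstate hemoglobin v1 (uM)\n")
        fh.write(f"# sampling_rate_hz\t{series.sampling_rate:g}\n")
        fh.write("# channels\t%s\n" % ",".join(series.channel_ids))
        fh.write("time_s\t" + "\t".join(cols) + "\n")
        for i, t in enumerate(series.time):
            vals = []
            for j in range(len(series.channel_ids)):
                vals += [series.hbo[i, j], series.hbr[i, j]]
            fh.write("%.6f\t" % t + "\t".join("%.10g" % v for v in vals) + "\n")
    if events_path is None:
        events_path = path.with_name(path.stem + "_events.tsv")
    write_events(series.events, events_path)


def read_hemo(path, events_path=None) -> HemoSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    header = None
    for ln in path.read_text(encoding="utf-8").splitlines():
        if ln.startswith("#"):
            parts = ln[1:].strip().split("\t")
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
            continue
        if header is None:
            header = ln.split("\t")
            continue
        rows.append([float(v) for v in ln.split("\t")])
    channel_ids = tuple(meta["channels"].split(","))
    data = np.asarray(rows)
    time = data[:, 0]
    body = data[:, 1:].reshape(len(rows), len(channel_ids), 2)
    if events_path is None:
        candidate = path.with_name(path.stem + "_events.tsv")
        events = read_events(candidate) if candidate.exists() else []
    else:
        events = read_events(events_path)
    return HemoSeries(
        time=time,
        hbo=body[:, :, 0],
        hbr=body[:, :, 1],
        channel_ids=channel_ids,
        sampling_rate=float(meta["sampling_rate_hz"]),
        events=events,
    )


# -- feature TSV --------------------------------------------------------------


def write_features(features: FeatureMatrix, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("label\t" + "\t".join(features.column_names) + "\n")
        for label, row in zip(features.labels, features.values):
            fh.write(label + "\t" + "\t".join("%.17g" % v for v in row) + "\n")


def read_features(path) -> FeatureMatrix:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    if header[0] != "label":
        raise ValueError("feature file must start with a 'label' column")
    labels, rows = [], []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return FeatureMatrix(
        values=np.asarray(rows), labels=labels, column_names=header[1:]
    )


# -- minimal SNIRF ------------------------------------------------------------


def write_snirf(rec: OpticalRecording, path) -> None:
    """Minimal SNIRF v1 container: dataTimeSeries/time/measurementList/stim."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset(
            "dataTimeSeries", data=rec.intensity.reshape(rec.n_samples, -1)
        )
        data.create_dataset("time", data=rec.time)
        k = 0
        for ci, cid in enumerate(rec.channel_ids):
            for wi, _wl in enumerate(rec.wavelengths_nm):
                k += 1
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=ci + 1)
                ml.create_dataset("detectorIndex", data=ci + 1)
                ml.create_dataset("wavelengthIndex", data=wi + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths_nm))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("channelIds", data=",".join(rec.channel_ids))
        meta.create_dataset("samplingRateHz", data=rec.sampling_rate)
        for i, label in enumerate(sorted({e[2] for e in rec.events})):
            stim = nirs.create_group(f"stim{i + 1}")
            stim.create_dataset("name", data=label)
            evs = [(o, d, 1.0) for o, d, lbl in rec.events if lbl == label]
            stim.create_dataset("data", data=np.asarray(evs))


def read_snirf(path, montage: MontageSpec | None = None) -> OpticalRecording:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        time = data["time"][()]
        flat = data["dataTimeSeries"][()]
        wavelengths = tuple(f["nirs/probe/wavelengths"][()])
        raw_ids = f["nirs/metaDataTags/channelIds"][()]
        if isinstance(raw_ids, bytes):
            raw_ids = raw_ids.decode()
        channel_ids = tuple(str(raw_ids).split(","))
        rate = float(f["nirs/metaDataTags/samplingRateHz"][()])
        events = []
        i = 1
        while f"nirs/stim{i}" in f:
            stim = f[f"nirs/stim{i}"]
            name = stim["name"][()]
            if isinstance(name, bytes):
                name = name.decode()
            for onset, dur, _amp in stim["data"][()]:
                events.append((float(onset), float(dur), str(name)))
            i += 1
        events.sort()
    intensity = flat.reshape(len(time), len(channel_ids), len(wavelengths))
    return OpticalRecording(
        time=time,
        intensity=intensity,
        channel_ids=channel_ids,
        wavelengths_nm=wavelengths,  # type: ignore[arg-type]
        sampling_rate=rate,
        events=events,
        montage=montage,
    )


# -- the end-to-end runner ----------------------------------------------------


def _digest(rec: OpticalRecording) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(rec.time).tobytes())
    h.update(np.ascontiguousarray(rec.intensity).tobytes())
    h.update(repr(sorted(rec.events)).encode())
    return h.hexdigest()[:16]


def process_recording(
    rec: OpticalRecording,
    config: PipelineConfig | None = None,
    montage: MontageSpec | None = None,
    constants: OpticsConstants | None = None,
) -> FeatureMatrix:
    """mbll → preprocess → features, under one configuration."""
    config = config or PipelineConfig()
    montage = montage or rec.montage or default_montage()
    constants = constants or default_constants()
    od = intensity_to_od(rec, config.baseline_window)
    hemo = od_to_hemoglobin(od, montage, constants)
    epochs = preprocess(
        hemo,
        offset=config.epoch_offset,
        duration=config.epoch_duration,
        order=config.filter_order,
        cutoff=config.filter_cutoff,
        filter_stage=config.filter_stage,
    )
    basis = build_basis(
        config.epoch_duration,
        hemo.sampling_rate,
        config.basis_sigma,
        config.basis_spacing,
    )
    return extract_features(epochs, basis, config.chromophore)


def run_session(
    config: PipelineConfig,
    recording: OpticalRecording,
    *,
    session: str = "calibration",
    subject_id: str = "sim",
    calibration_features: FeatureMatrix | None = None,
    montage: MontageSpec | None = None,
    constants: OpticsConstants | None = None,
) -> tuple[SubjectResult, RunManifest, CvResult | None, FeatureMatrix]:
    """Run the full pipeline on one recording.

    ``calibration`` mode cross-validates; ``online`` mode trains on the
    supplied calibration features and replays the recording's epochs as
    a decision stream.
    """
    montage = montage or recording.montage or default_montage()
    constants = constants or default_constants()
    manifest = RunManifest(
        config=config.to_dict(),
        package_version=__version__,
        input_digest=_digest(recording),
        session=session,
        n_samples=recording.n_samples,
        n_channels_long=len(montage.long_channels),
    )
    try:
        od = intensity_to_od(recording, config.baseline_window)
        hemo = od_to_hemoglobin(od, montage, constants)
        epochs = preprocess(
            hemo,
            offset=config.epoch_offset,
            duration=config.epoch_duration,
            order=config.filter_order,
            cutoff=config.filter_cutoff,
            filter_stage=config.filter_stage,
        )
        manifest.n_epochs = len(epochs)
        manifest.n_epochs_dropped = epochs.n_dropped
        manifest.class_counts = dict(epochs.class_counts)
        basis = build_basis(
            config.epoch_duration,
            hemo.sampling_rate,
            config.basis_sigma,
            config.basis_spacing,
        )
        features = extract_features(epochs, basis, config.chromophore)
        if session == "calibration":
            cv = crossvalidate(features, config.cv_folds, config.svm_c, config.seed)
            manifest.fold_assignment = cv.fold_assignment
            accuracy = cv.mean_accuracy
        elif session == "online":
            if calibration_features is None:
                raise ValueError("online mode requires calibration features")
            _preds, accuracy, _model = replay_online(
                calibration_features, features, config.svm_c
            )
            cv = None
        else:
            raise ValueError("session must be 'calibration' or 'online'")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in session {session!r}: {exc}") from exc
    manifest.accuracy_pct = accuracy
    result = SubjectResult(subject_id=subject_id, session=session, accuracy=accuracy)
    return result, manifest, cv, features
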