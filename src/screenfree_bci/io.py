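"""Readers and writers for recordings, schedules, epochs, models, configs.

Continuous EEG comes in as BrainVision (.vhdr/.vmrk/.eeg triplet) or EDF —
both read through MNE — or as this package's self-describing HDF5
container.  Event schedules and results travel as TSV; run configuration
as YAML.  All containers carry units, rates and a schema version so files
are interpretable without outside context.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .data import SCHEDULE_COLUMNS, ContinuousRecording, EpochSet, EventSchedule
from .decoding import LDAModel, PipelineModel
from .preprocessing import PrototypePair, XdawnModel

__all__ = [
    "RunConfig",
    "read_recording",
    "write_recording",
    "read_schedule",
    "write_schedule",
    "write_epochs",
    "read_epochs",
    "save_model",
    "load_model",
]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Resolved analysis configuration with the protocol defaults."""

    band_low_hz: float = 0.5
    band_high_hz: float = 16.0
    out_rate_hz: float = 100.0
    window_s: tuple = (0.0, 1.0)
    baseline_s: tuple = (-0.2, 0.0)
    rejection_uv: float = 100.0
    variant: str = "cts_reg_lda"
    subclass_definition: str = "object"  # object | position_group | position
    cv_folds: int = 5
    data_fraction: float = 1.0
    seeds: tuple = (0,)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window_s", "baseline_s", "seeds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# continuous recordings


def read_recording(path, format: str = "container") -> ContinuousRecording:
    """Read continuous EEG; output is always channels x samples in uV."""
    path = Path(path)
    if format == "container":
        return _read_container(path)
    if format in ("brainvision", "edf"):
        import mne

        if format == "brainvision":
            if path.suffix != ".vhdr":
                raise ValueError("BrainVision reading expects the .vhdr header")
            for ext in (".vmrk", ".eeg"):
                if not path.with_suffix(ext).exists():
                    raise FileNotFoundError(
                        f"BrainVision triplet member missing: {path.with_suffix(ext)}"
                    )
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # MNE uses volts internally
        return ContinuousRecording(
            data=data, rate=float(raw.info["sfreq"]), channel_names=list(raw.ch_names)
        )
    raise ValueError(f"unsupported format {format!r}")


def _read_container(path: Path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        grp = f["recording"]
        data = grp["data"][()]
        rate = float(grp.attrs["rate_hz"])
        declared = int(grp.attrs["n_samples"])
        if declared != data.shape[1]:
            raise ValueError(
                f"header declares {declared} samples but data has {data.shape[1]}"
            )
        units = grp.attrs["units"]
        if units == "V":
            data = data * 1e6
        elif units != "uV":
            raise ValueError(f"ambiguous units {units!r}; expected 'uV' or 'V'")
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in grp.attrs["channel_names"]
        ]
    return ContinuousRecording(data=data, rate=rate, channel_names=names)


def write_recording(rec: ContinuousRecording, path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("recording")
        grp.create_dataset("data", data=rec.data)
        grp.attrs["rate_hz"] = rec.rate
        grp.attrs["n_samples"] = rec.n_samples
        grp.attrs["units"] = "uV"
        grp.attrs["channel_names"] = [n.encode() for n in rec.channel_names]
        grp.attrs["schema_version"] = SCHEMA_VERSION


# ---------------------------------------------------------------------------
# schedules


def read_schedule(path) -> EventSchedule:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in SCHEDULE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"schedule TSV is missing columns: {missing}")
    onsets = frame["onset_s"].to_numpy(dtype=float)
    dup = np.nonzero(np.diff(onsets) == 0)[0]
    if dup.size:
        raise ValueError(f"duplicated onset timestamps at rows {(dup + 2).tolist()[:5]}")
    sched = EventSchedule(frame)
    missing = [
        int(t) for t, grp in sched.frame.groupby("trial")
        if not grp["is_target"].any()
    ]
    if missing:
        raise ValueError(f"trials without a target object: {missing[:5]}")
    return sched


def write_schedule(sched: EventSchedule, path) -> None:
    sched.frame.loc[:, list(SCHEDULE_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# epochs


def write_epochs(ep: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("epochs")
        grp.create_dataset("windows", data=ep.windows)
        grp.create_dataset("rejected_mask", data=ep.rejected_mask)
        grp.attrs["rate_hz"] = ep.rate
        grp.attrs["units"] = "uV"
        grp.attrs["schema_version"] = SCHEMA_VERSION
        sched = f.create_group("schedule")
        for col in SCHEDULE_COLUMNS:
            sched.create_dataset(col, data=ep.schedule.frame[col].to_numpy())


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        grp = f["epochs"]
        windows = grp["windows"][()]
        rejected = grp["rejected_mask"][()]
        rate = float(grp.attrs["rate_hz"])
        frame = pd.DataFrame(
            {col: f["schedule"][col][()] for col in SCHEDULE_COLUMNS}
        )
    return EpochSet(
        windows=windows, schedule=EventSchedule(frame), rate=rate,
        rejected_mask=rejected,
    )


# ---------------------------------------------------------------------------
# fitted pipeline models


def _write_lda(grp: h5py.Group, lda: LDAModel) -> None:
    for name in ("w", "mu_t", "mu_nt", "C_lda"):
        grp.create_dataset(name, data=getattr(lda, name))
    grp.attrs["b"] = lda.b


def _read_lda(grp: h5py.Group) -> LDAModel:
    return LDAModel(
        w=grp["w"][()], b=float(grp.attrs["b"]), mu_t=grp["mu_t"][()],
        mu_nt=grp["mu_nt"][()], C_lda=grp["C_lda"][()],
    )


def save_model(model: PipelineModel, path) -> None:
    """Serialize a fitted pipeline to a single versioned HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["variant"] = model.variant
        f.attrs["subclass_definition"] = model.subclass_definition
        f.create_dataset("proto/target_mean", data=model.proto.target_mean)
        f.create_dataset("proto/nontarget_mean", data=model.proto.nontarget_mean)
        f.create_dataset("xdawn/Wt", data=model.xdawn.Wt)
        f.create_dataset("xdawn/Wnt", data=model.xdawn.Wnt)
        f.create_dataset("global_ref", data=model.global_ref)
        _write_lda(f.create_group("global_lda"), model.global_lda)
        for j, ref in model.subclass_refs.items():
            g = f.create_group(f"subclass/{j}")
            g.create_dataset("ref", data=ref)
            _write_lda(g.create_group("lda"), model.subclass_ldas[j])
        alphas = {
            f"{j}|{int(cls)}": {"ids": [int(i) for i in ids],
                                "alpha": np.asarray(a).tolist()}
            for (j, cls), (ids, a) in model.mts_alpha.items()
        }
        f.attrs["mts_alpha_json"] = json.dumps(alphas)


def load_model(path) -> PipelineModel:
    with h5py.File(path, "r") as f:
        if int(f.attrs["schema_version"]) != SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        model = PipelineModel(
            variant=str(f.attrs["variant"]),
            subclass_definition=str(f.attrs["subclass_definition"]),
            proto=PrototypePair(
                target_mean=f["proto/target_mean"][()],
                nontarget_mean=f["proto/nontarget_mean"][()],
            ),
            xdawn=XdawnModel(Wt=f["xdawn/Wt"][()], Wnt=f["xdawn/Wnt"][()]),
            global_ref=f["global_ref"][()],
            global_lda=_read_lda(f["global_lda"]),
        )
        if "subclass" in f:
            for key in f["subclass"]:
                j = int(key)
                model.subclass_refs[j] = f[f"subclass/{key}/ref"][()]
                model.subclass_ldas[j] = _read_lda(f[f"subclass/{key}/lda"])
        for key, rec in json.loads(f.attrs["mts_alpha_json"]).items():
            j, cls = key.split("|")
            model.mts_alpha[(int(j), bool(int(cls)))] = (
                rec["ids"], np.asarray(rec["alpha"]),
            )
    return model
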