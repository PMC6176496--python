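"""File formats: TSV events, HDF5 array containers, CSV atlas/tables, JSON config.

Every HDF5 container carries provenance attributes (package version, config
hash when supplied) and round-trips losslessly. Raw EEG can be read from EDF
through mne's bundled reader or from the HDF5 container.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import ConfigError, RunConfig
from .connectivity import ConnectivityMatrix, ROISignals
from .inverse import LeadField
from .network import ConnectionMetrics, DensitySweep
from .preprocess import EpochSet, RawRecording
from .simulate import EventSequence


class FormatError(ValueError):
    """Raised for malformed or unrecognized input files."""


def _version() -> str:
    from . import __version__
    return __version__


def _stamp(group, config_hash: str | None) -> None:
    group.attrs["package_version"] = _version()
    if config_hash is not None:
        group.attrs["config_hash"] = config_hash


def _check_hash(group, config_hash: str | None, path) -> None:
    if config_hash is not None and "config_hash" in group.attrs:
        found = group.attrs["config_hash"]
        if found != config_hash:
            raise FormatError(
                f"{path}: config hash mismatch ({found} != {config_hash}); "
                "refusing to mix outputs from different configurations")


# -- events ----------------------------------------------------------------

def write_events_tsv(events: EventSequence, path) -> None:
    pd.DataFrame({"onset_ms": events.onsets_ms, "label": events.labels,
                  "block": events.blocks}).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> EventSequence:
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_ms", "label", "block"):
        if col not in df.columns:
            raise FormatError(f"{path}: events TSV missing column {col!r}")
    return EventSequence(df["onset_ms"].to_numpy(float),
                         df["label"].to_numpy(str),
                         df["block"].to_numpy(int), validate_spacing=False)


# -- HDF5 containers -------------------------------------------------------

def save_roi_signals(signals: ROISignals, path,
                     config_hash: str | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=signals.data)
        f.create_dataset("labels", data=np.asarray(signals.labels, dtype="S"))
        f.attrs["sampling_rate_hz"] = signals.sampling_rate_hz
        f.attrs["tmin_ms"] = signals.tmin_ms
        f.attrs["state"] = signals.state
        _stamp(f, config_hash)


def load_roi_signals(path, config_hash: str | None = None) -> ROISignals:
    with h5py.File(path, "r") as f:
        if "signals" not in f:
            raise FormatError(f"{path}: missing 'signals' dataset")
        _check_hash(f, config_hash, path)
        return ROISignals(f["signals"][()],
                          float(f.attrs["sampling_rate_hz"]),
                          float(f.attrs["tmin_ms"]),
                          labels=f["labels"][()].astype(str),
                          state=str(f.attrs["state"]))


def save_epochs(epochs: EpochSet, path, config_hash: str | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
        f.create_dataset("labels", data=np.asarray(epochs.labels, dtype="S"))
        f.create_dataset("channel_names",
                         data=np.asarray(epochs.channel_names, dtype="S"))
        f.attrs["sampling_rate_hz"] = epochs.sampling_rate_hz
        f.attrs["tmin_ms"] = epochs.tmin_ms
        f.attrs["rejected_log"] = json.dumps(epochs.rejected_log)
        _stamp(f, config_hash)


def load_epochs(path, config_hash: str | None = None) -> EpochSet:
    with h5py.File(path, "r") as f:
        if "epochs" not in f:
            raise FormatError(f"{path}: missing 'epochs' dataset")
        _check_hash(f, config_hash, path)
        return EpochSet(f["epochs"][()], f["labels"][()].astype(str),
                        [c.decode() for c in f["channel_names"][()]],
                        float(f.attrs["sampling_rate_hz"]),
                        float(f.attrs["tmin_ms"]),
                        rejected_log=json.loads(f.attrs["rejected_log"]))


def save_connectivity(matrix: ConnectivityMatrix, path,
                      config_hash: str | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("wpli", data=matrix.w)
        f.attrs["n_trials"] = matrix.n_trials
        f.attrs["state"] = matrix.state
        f.attrs["condition"] = matrix.condition
        _stamp(f, config_hash)


def load_connectivity(path, config_hash: str | None = None) -> ConnectivityMatrix:
    with h5py.File(path, "r") as f:
        if "wpli" not in f:
            raise FormatError(f"{path}: missing 'wpli' dataset")
        _check_hash(f, config_hash, path)
        return ConnectivityMatrix(f["wpli"][()], int(f.attrs["n_trials"]),
                                  str(f.attrs["state"]),
                                  str(f.attrs["condition"]))


def save_leadfield(lf: LeadField, path, config_hash: str | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("sensor_names",
                         data=np.asarray(lf.sensor_names, dtype="S"))
        f.create_dataset("source_ids", data=np.asarray(lf.source_ids))
        _stamp(f, config_hash)


def load_leadfield(path, config_hash: str | None = None) -> LeadField:
    with h5py.File(path, "r") as f:
        if "gain" not in f:
            raise FormatError(f"{path}: missing 'gain' dataset")
        _check_hash(f, config_hash, path)
        return LeadField(f["gain"][()],
                         [c.decode() for c in f["sensor_names"][()]],
                         f["source_ids"][()])


def save_raw(recording: RawRecording, path,
             config_hash: str | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.create_dataset("channel_names",
                         data=np.asarray(recording.channel_names, dtype="S"))
        f.attrs["sampling_rate_hz"] = recording.sampling_rate_hz
        f.attrs["reference_scheme"] = recording.reference_scheme
        _stamp(f, config_hash)


def read_raw(path) -> RawRecording:
    """Read continuous EEG from .edf (mne reader) or the HDF5 container.

    EDF channel units are converted to microvolts; stimulus events are
    expected in a separate TSV (an EDF without an event channel is fine).
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return RawRecording(raw.get_data() * 1e6, raw.ch_names,
                            float(raw.info["sfreq"]),
                            reference_scheme="as-recorded")
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise FormatError(f"{path}: missing 'data' dataset")
            return RawRecording(f["data"][()],
                                [c.decode() for c in f["channel_names"][()]],
                                float(f.attrs["sampling_rate_hz"]),
                                str(f.attrs["reference_scheme"]))
    raise FormatError(f"unrecognized raw format: {path}")


# -- metrics / tables ------------------------------------------------------

def sweep_to_frame(sweep: DensitySweep, **labels) -> pd.DataFrame:
    """Flatten a density sweep (plus its summary row) to a DataFrame."""
    from .atlas import AREA_CODES

    def row(m: ConnectionMetrics, summary: bool) -> dict:
        r = {"density": m.density, "l_all": m.l_all, "s_all": m.s_all,
             "ratio": m.ratio, "is_summary": summary, **labels}
        for a, lk, sk in zip(AREA_CODES[:len(m.l_k)], m.l_k, m.s_k):
            r[f"L_{a}"] = lk
            r[f"S_{a}"] = sk
        return r

    rows = [row(m, False) for m in sweep.per_density]
    rows.append(row(sweep.summary, True))
    return pd.DataFrame(rows)


def write_tables(tables: dict[str, pd.DataFrame], out_dir,
                 config_hash: str | None = None) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, tab in tables.items():
        p = out_dir / f"{name}.csv"
        tab = tab.copy()
        if config_hash is not None:
            tab["config_hash"] = config_hash
        tab.to_csv(p, index=False)
        written.append(p)
    return written


# -- config ----------------------------------------------------------------

def read_config(path) -> RunConfig:
    text = Path(path).read_text()
    try:
        return RunConfig.from_json(text)
    except (json.JSONDecodeError, TypeError) as err:
        raise FormatError(f"{path}: malformed config: {err}") from err


def write_config(config: RunConfig, path) -> None:
    Path(path).write_text(config.to_json())


def validate_events_against_raw(events: EventSequence,
                                recording: RawRecording) -> None:
    """Reject event tables that overrun the recording."""
    end_ms = recording.n_samples * 1000.0 / recording.sampling_rate_hz
    if len(events) and events.onsets_ms[-1] >= end_ms:
        raise FormatError(
            f"last event at {events.onsets_ms[-1]:.0f} ms lies beyond the "
            f"recording end ({end_ms:.0f} ms): sampling-rate mismatch?")
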