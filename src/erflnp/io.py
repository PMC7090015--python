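"""File formats: HDF5 trace containers, CSV spike/metric tables, YAML configs.

Stimulus container layout: datasets ``/stimulus`` (standardized current)
and ``/voltage`` (command), attributes ``sampling_rate``, ``seed`` and the
standardization constants.  Spike tables are CSV with columns
``cell_id, repetition, time_s`` (seconds, 6 decimals).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import RawTrace, SpikeTrain, StimulusTrace, VoltageCommand

__all__ = [
    "save_stimulus", "load_stimulus", "save_raw", "load_raw",
    "save_spikes", "load_spikes", "spikes_to_frame",
    "save_yaml", "load_yaml", "stimulus_to_csv",
]


def save_stimulus(path: str | Path, stimulus: StimulusTrace,
                  command: VoltageCommand | None = None,
                  seed: int | None = None) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("stimulus", data=stimulus.samples, track_times=False)
        f.attrs["sampling_rate"] = stimulus.sampling_rate
        if seed is not None:
            f.attrs["seed"] = seed
        if stimulus.standardization is not None:
            d.attrs["standardization_mean"] = stimulus.standardization[0]
            d.attrs["standardization_sd"] = stimulus.standardization[1]
        if command is not None:
            v = f.create_dataset("voltage", data=command.volts, track_times=False)
            v.attrs["capacitance_scale"] = command.capacitance_scale


def load_stimulus(path: str | Path) -> tuple[StimulusTrace, VoltageCommand | None]:
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["sampling_rate"])
        d = f["stimulus"]
        std = None
        if "standardization_mean" in d.attrs:
            std = (float(d.attrs["standardization_mean"]),
                   float(d.attrs["standardization_sd"]))
        stim = StimulusTrace(d[:], fs, standardization=std)
        cmd = None
        if "voltage" in f:
            v = f["voltage"]
            cmd = VoltageCommand(v[:], fs,
                                 float(v.attrs.get("capacitance_scale", 1.0)))
    return stim, cmd


def save_raw(path: str | Path, raw: RawTrace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("raw", data=raw.samples, track_times=False)
        f.attrs["sampling_rate"] = raw.sampling_rate


def load_raw(path: str | Path) -> RawTrace:
    with h5py.File(path, "r") as f:
        return RawTrace(f["raw"][:], float(f.attrs["sampling_rate"]))


def spikes_to_frame(trains: list[SpikeTrain]) -> pd.DataFrame:
    rows = [(tr.cell_id, tr.repetition_id, round(float(t), 6))
            for tr in trains for t in tr.times]
    return pd.DataFrame(rows, columns=["cell_id", "repetition", "time_s"])


def save_spikes(path: str | Path, trains: list[SpikeTrain]) -> None:
    spikes_to_frame(trains).to_csv(path, index=False, float_format="%.6f")


def load_spikes(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for (cell, rep), grp in df.groupby(["cell_id", "repetition"], sort=True):
        trains.append(SpikeTrain(np.sort(grp["time_s"].to_numpy(dtype=float)),
                                 repetition_id=int(rep), cell_id=str(cell)))
    return trains


def stimulus_to_csv(path: str | Path, stimulus: StimulusTrace) -> None:
    pd.DataFrame({"sample_index": np.arange(stimulus.n_samples),
                  "value": stimulus.samples}).to_csv(path, index=False)


def save_yaml(path: str | Path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
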