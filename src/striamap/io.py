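"""Tabular I/O: puncta CSV, sweep CSV + metadata sidecar, assignment TSV.

Formats
-------
Puncta CSV (header required, '.' decimal, UTF-8)::

    channel,x_um,y_um,z_um,diameter_um

Sweeps CSV: ``sweep_id,time_ms,voltage_mV`` with a sidecar metadata table
``sweep_id,current_pA,onset_ms,offset_ms``.

Assignments TSV: one row per retained input with channel, compartment,
attach segment/fraction, edge distance and soma path distance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .morphology import Compartment
from .puncta import AssignedInput, Channel, Punctum
from .ephys import SweepRecording

PUNCTA_COLUMNS = ["channel", "x_um", "y_um", "z_um", "diameter_um"]


def read_puncta_csv(path: str | Path) -> list[Punctum]:
    df = pd.read_csv(path)
    missing = [c for c in PUNCTA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing puncta columns {missing}")
    return [
        Punctum(
            channel=Channel[str(row.channel)],
            center=np.array([row.x_um, row.y_um, row.z_um]),
            diameter=float(row.diameter_um),
        )
        for row in df.itertuples()
    ]


def write_puncta_csv(puncta: Sequence[Punctum], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "channel": [p.channel.value for p in puncta],
            "x_um": [p.center[0] for p in puncta],
            "y_um": [p.center[1] for p in puncta],
            "z_um": [p.center[2] for p in puncta],
            "diameter_um": [p.diameter for p in puncta],
        }
    )
    df.to_csv(path, index=False)


def write_assignments_tsv(inputs: Sequence[AssignedInput], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "channel": [i.channel.value for i in inputs],
            "compartment": [i.compartment.value for i in inputs],
            "attach_segment": [i.attach[0] for i in inputs],
            "attach_fraction": [i.attach[1] for i in inputs],
            "edge_distance_um": [i.edge_distance for i in inputs],
            "soma_path_distance_um": [i.soma_path_distance for i in inputs],
            "x_um": [i.center[0] for i in inputs],
            "y_um": [i.center[1] for i in inputs],
            "z_um": [i.center[2] for i in inputs],
            "diameter_um": [i.punctum.diameter for i in inputs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_assignments_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sweeps_csv(sweeps: Sequence[SweepRecording], data_path: str | Path, meta_path: str | Path) -> None:
    frames = [
        pd.DataFrame({"sweep_id": s.sweep_id, "time_ms": s.time, "voltage_mV": s.voltage})
        for s in sweeps
    ]
    pd.concat(frames, ignore_index=True).to_csv(data_path, index=False, float_format="%.9g")
    meta = pd.DataFrame(
        {
            "sweep_id": [s.sweep_id for s in sweeps],
            "current_pA": [s.current_step for s in sweeps],
            "onset_ms": [s.step_window[0] for s in sweeps],
            "offset_ms": [s.step_window[1] for s in sweeps],
        }
    )
    meta.to_csv(meta_path, index=False)


def read_sweeps_csv(data_path: str | Path, meta_path: str | Path) -> list[SweepRecording]:
    data = pd.read_csv(data_path)
    meta = pd.read_csv(meta_path).set_index("sweep_id")
    sweeps = []
    for sid, grp in data.groupby("sweep_id", sort=True):
        row = meta.loc[sid]
        sweeps.append(
            SweepRecording(
                time=grp["time_ms"].to_numpy(),
                voltage=grp["voltage_mV"].to_numpy(),
                current_step=float(row["current_pA"]),
                step_window=(float(row["onset_ms"]), float(row["offset_ms"])),
                sweep_id=int(sid),
            )
        )
    return sweeps
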