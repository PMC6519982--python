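"""CSV/JSON readers and writers for the exchange formats.

QuantalTrain: tidy CSV (stim_time_s, quanta, sweep_group).
SweepTrace:   two-column CSV (time_s, current_nA) + JSON sidecar.
FMTrace:      wide CSV (frame_time_s, roi_0..roi_k, background) + JSON sidecar
              carrying the epochs.
MiniCatalog:  tidy CSV (event_time_s, amplitude_nA, charge_pC).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import PvEstimate, RRPEstimate
from .fm import FMTrace
from .measure import MiniCatalog
from .simulate import QuantalTrain, SweepTrace

__all__ = [
    "write_quantal_train", "read_quantal_train",
    "write_sweep", "read_sweep",
    "write_fm_trace", "read_fm_trace",
    "write_mini_catalog", "read_mini_catalog",
    "estimate_record", "estimates_table",
]


def write_quantal_train(train: QuantalTrain, path, sweep_group: int = 0) -> None:
    pd.DataFrame({
        "stim_time_s": train.stim_times,
        "quanta": train.quanta,
        "sweep_group": sweep_group,
    }).to_csv(path, index=False)


def read_quantal_train(path) -> QuantalTrain | dict:
    """Read one train, or a dict {sweep_group: train} if several groups."""
    df = pd.read_csv(path)
    groups = df["sweep_group"].unique() if "sweep_group" in df else [0]
    out = {}
    for g in groups:
        sub = df[df["sweep_group"] == g] if "sweep_group" in df else df
        out[int(g)] = QuantalTrain(sub["stim_time_s"].to_numpy(float),
                                   sub["quanta"].to_numpy(float))
    return out if len(out) > 1 else next(iter(out.values()))


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def write_sweep(sweep: SweepTrace, path) -> None:
    pd.DataFrame({"time_s": sweep.times, "current_nA": sweep.current}).to_csv(
        path, index=False)
    meta = {
        "sample_rate": sweep.sample_rate,
        "stim_times": sweep.stim_times.tolist(),
        "quantal_waveform": list(sweep.quantal_waveform),
        "noise_sd": sweep.noise_sd,
        "t0": sweep.t0,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_sweep(path) -> SweepTrace:
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    return SweepTrace(meta["sample_rate"], df["current_nA"].to_numpy(float),
                      np.asarray(meta["stim_times"], dtype=float),
                      tuple(meta.get("quantal_waveform", (1e-4, 5e-4, None))),
                      meta.get("noise_sd", 0.0), meta.get("t0", 0.0))


def write_fm_trace(trace: FMTrace, path) -> None:
    cols = {"frame_time_s": trace.frame_times}
    for i in range(trace.n_rois):
        cols[f"roi_{i}"] = trace.roi_values[i]
    cols["background"] = trace.background
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {"epochs": {k: list(v) for k, v in trace.epochs.items()}}
    if trace.stained_total is not None:
        meta["stained_total"] = trace.stained_total.tolist()
    _sidecar(path).write_text(json.dumps(meta))


def read_fm_trace(path) -> FMTrace:
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    roi_cols = [c for c in df.columns if c.startswith("roi_")]
    stained = meta.get("stained_total")
    return FMTrace(df["frame_time_s"].to_numpy(float),
                   df[roi_cols].to_numpy(float).T,
                   df["background"].to_numpy(float),
                   {k: tuple(v) for k, v in meta["epochs"].items()},
                   stained_total=np.asarray(stained) if stained is not None else None)


def write_mini_catalog(catalog: MiniCatalog, path) -> None:
    pd.DataFrame({
        "event_time_s": catalog.event_times,
        "amplitude_nA": catalog.amplitudes,
        "charge_pC": catalog.charges,
    }).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({"recording_duration": catalog.recording_duration}))


def read_mini_catalog(path) -> MiniCatalog:
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    return MiniCatalog(df["event_time_s"].to_numpy(float),
                       df["amplitude_nA"].to_numpy(float),
                       df["charge_pC"].to_numpy(float),
                       meta["recording_duration"])


def estimate_record(est: RRPEstimate, pv: PvEstimate | None = None,
                    preparation: str = "") -> dict:
    """Flatten an estimate into one JSON/CSV-friendly record."""
    rec = {
        "preparation": preparation,
        "method": est.method,
        "rrp0": est.rrp0,
        "recruitment_total": est.recruitment_total,
        "alpha_used": est.alpha_used,
        "fit_residual": est.fit_residual,
        "converged": est.converged,
    }
    if est.capacity is not None:
        rec["capacity"] = est.capacity
    if est.pv_fit is not None:
        rec["pv_fit"] = est.pv_fit
    if pv is not None:
        rec["pv_bar"] = pv.pv_bar
        rec["pv_context"] = pv.context
    return rec


def estimates_table(records) -> pd.DataFrame:
    """Tidy table across preparations: one row per preparation x method."""
    return pd.DataFrame(list(records))


def dataclass_to_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(
        dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else obj,
        default=default, indent=2))
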