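"""Reading and writing of session bundles, event tables, and HDF5 archives.

The on-disk session bundle is a plain-text directory layout::

    session/
      protocol.json            # trial structure + simulation metadata
      traces/trial_001.csv     # time_s, vm_mV (or im_pA)
      ventral_root/trial_001.csv   # time_s, vr_au
      ground_truth.json        # optional; absent for real recordings

CSV is the canonical interchange format (inspectable, language-neutral);
HDF5 is an export, not the native store.  Event-table times are written to
1 µs and conductances to 1 pS so that read∘write round-trips are exact at
declared precision.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

EVENT_LABELS = ("complex", "simple", "pfEPSP")

EVENT_TABLE_COLUMNS = [
    "cell_id",
    "trial_index",
    "time_s",
    "label",
    "peak_dvdt_mv_per_ms",
    "conductance_ns",
    "normalized_conductance",
    "in_cs_window",
    "in_illumination",
]


class BundleFormatError(ValueError):
    """A session bundle on disk violates the layout or sampling contract."""


@dataclass
class TraceRecording:
    """A uniformly sampled single-channel recording.

    ``values`` are mV for current clamp, pA for voltage clamp, and
    arbitrary units for ventral-root recordings.  Time is seconds from
    sweep start; sample ``i`` sits at ``i / sampling_rate``.
    """

    values: np.ndarray
    sampling_rate: float
    modality: str = "current_clamp"  # current_clamp | voltage_clamp | ventral_root
    capacitance: Optional[float] = None  # pF, current clamp only
    holding_potential: Optional[float] = None  # mV, voltage clamp only
    cell_id: str = "cell"
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in ("current_clamp", "voltage_clamp", "ventral_root"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.modality in ("current_clamp", "voltage_clamp") and self.sampling_rate < 10_000:
            raise ValueError(
                "intracellular recordings require sampling_rate >= 10 kHz "
                f"(got {self.sampling_rate:g} Hz)"
            )
        if self.modality == "voltage_clamp" and self.holding_potential is None:
            self.holding_potential = -60.0

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate


# ---------------------------------------------------------------------------
# session bundles
# ---------------------------------------------------------------------------

def _trace_filename(i: int) -> str:
    return f"trial_{i:03d}.csv"


def _write_trace_csv(path: str, trace: TraceRecording, value_col: str) -> None:
    t = trace.times
    with open(path, "w") as fh:
        fh.write(f"time_s,{value_col}\n")
        for ti, vi in zip(t, trace.values):
            fh.write(f"{ti:.6f},{vi:.6f}\n")


def _read_trace_csv(path: str, sampling_rate_hint: Optional[float] = None):
    df = pd.read_csv(path)
    if df.shape[1] != 2 or "time_s" != df.columns[0]:
        raise BundleFormatError(f"malformed trace CSV {path!r}: expected time_s,<value>")
    t = df["time_s"].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise BundleFormatError(f"trace CSV {path!r} has fewer than 2 samples")
    dt = (t[-1] - t[0]) / (t.size - 1)
    if dt <= 0:
        raise BundleFormatError(f"non-increasing timestamps in {path!r}")
    expected = t[0] + dt * np.arange(t.size)
    if np.max(np.abs(t - expected)) >= 0.5 * dt:
        raise BundleFormatError(f"non-uniform sampling in {path!r}")
    fs = 1.0 / dt
    if sampling_rate_hint is not None and abs(fs - sampling_rate_hint) / sampling_rate_hint > 0.01:
        raise BundleFormatError(
            f"sampling rate of {path!r} ({fs:.1f} Hz) disagrees with protocol metadata"
        )
    return v, fs, df.columns[1]


def write_session(bundle, path: str) -> None:
    """Write a :class:`~swimsort.synthetic.SessionBundle` to a directory."""
    os.makedirs(path, exist_ok=True)
    os.makedirs(os.path.join(path, "traces"), exist_ok=True)
    os.makedirs(os.path.join(path, "ventral_root"), exist_ok=True)

    meta = {
        "seed": bundle.seed,
        "cell_id": bundle.traces[0].cell_id if bundle.traces else "cell",
        "capacitance": bundle.traces[0].capacitance if bundle.traces else None,
        "sampling_rate": bundle.traces[0].sampling_rate if bundle.traces else None,
        "vr_sampling_rate": bundle.ventral_root[0].sampling_rate if bundle.ventral_root else None,
        "config": bundle.config,
        "trials": [p.to_dict() for p in bundle.protocol],
    }
    with open(os.path.join(path, "protocol.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)

    for trace in bundle.traces:
        col = "im_pA" if trace.modality == "voltage_clamp" else "vm_mV"
        _write_trace_csv(
            os.path.join(path, "traces", _trace_filename(trace.trial_index)), trace, col
        )
    for vr in bundle.ventral_root:
        _write_trace_csv(
            os.path.join(path, "ventral_root", _trace_filename(vr.trial_index)), vr, "vr_au"
        )
    if bundle.ground_truth is not None:
        with open(os.path.join(path, "ground_truth.json"), "w") as fh:
            json.dump(bundle.ground_truth.to_dict(), fh, indent=1, sort_keys=True)


def read_session(path: str):
    """Read a session bundle directory; the inverse of :func:`write_session`.

    ``ground_truth.json`` is optional (real-data mode).
    """
    from .synthetic import GroundTruth, SessionBundle, TrialProtocol

    proto_path = os.path.join(path, "protocol.json")
    if not os.path.exists(proto_path):
        raise BundleFormatError(f"missing protocol.json in {path!r}")
    with open(proto_path) as fh:
        meta = json.load(fh)
    protocol = [TrialProtocol.from_dict(d) for d in meta["trials"]]

    traces = []
    ventral = []
    for p in protocol:
        tpath = os.path.join(path, "traces", _trace_filename(p.trial_index))
        if os.path.exists(tpath):
            v, fs, col = _read_trace_csv(tpath, meta.get("sampling_rate"))
            traces.append(
                TraceRecording(
                    v,
                    fs,
                    modality="voltage_clamp" if col == "im_pA" else "current_clamp",
                    capacitance=meta.get("capacitance"),
                    cell_id=meta.get("cell_id", "cell"),
                    trial_index=p.trial_index,
                )
            )
        vpath = os.path.join(path, "ventral_root", _trace_filename(p.trial_index))
        if os.path.exists(vpath):
            v, fs, _ = _read_trace_csv(vpath, meta.get("vr_sampling_rate"))
            ventral.append(
                TraceRecording(
                    v, fs, modality="ventral_root",
                    cell_id=meta.get("cell_id", "cell"), trial_index=p.trial_index,
                )
            )

    gt = None
    gt_path = os.path.join(path, "ground_truth.json")
    if os.path.exists(gt_path):
        with open(gt_path) as fh:
            gt = GroundTruth.from_dict(json.load(fh))

    return SessionBundle(
        protocol=protocol,
        traces=traces,
        ventral_root=ventral,
        ground_truth=gt,
        config=meta.get("config"),
        seed=meta.get("seed"),
    )


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=d) for c, d in zip(
        EVENT_TABLE_COLUMNS,
        [str, int, float, str, float, float, float, bool, bool],
    )})


def write_event_table(events: pd.DataFrame, path: str) -> None:
    """Write a detected-event table as CSV (times to 1 µs, conductances to 1 pS)."""
    df = events.copy()
    for c in EVENT_TABLE_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan if c == "normalized_conductance" else pd.NA
    bad = ~df["label"].isin(EVENT_LABELS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unknown event label {df['label'].iloc[row]!r} in row {row}")
    df = df[EVENT_TABLE_COLUMNS]
    df = df.sort_values(["cell_id", "trial_index", "time_s"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write(",".join(EVENT_TABLE_COLUMNS) + "\n")
        for r in df.itertuples(index=False):
            norm = "" if pd.isna(r.normalized_conductance) else f"{r.normalized_conductance:.6f}"
            fh.write(
                f"{r.cell_id},{r.trial_index},{r.time_s:.6f},{r.label},"
                f"{r.peak_dvdt_mv_per_ms:.4f},{r.conductance_ns:.3f},{norm},"
                f"{int(bool(r.in_cs_window))},{int(bool(r.in_illumination))}\n"
            )


def read_event_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "label": str})
    missing = [c for c in EVENT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path!r} missing columns {missing}")
    bad = ~df["label"].isin(EVENT_LABELS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unknown event label {df['label'].iloc[row]!r} in row {row}")
    df["in_cs_window"] = df["in_cs_window"].astype(bool)
    df["in_illumination"] = df["in_illumination"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# HDF5 export
# ---------------------------------------------------------------------------

def export_hdf5(bundle, path: str, events: Optional[pd.DataFrame] = None) -> None:
    """Export a session bundle to a single HDF5 archive.

    Layout: ``/acquisition/trial_NNN`` (intracellular series, sampling rate
    and capacitance as attributes), ``/ventral_root/trial_NNN``, ``/epochs``
    (one group per trial with the protocol fields), and ``/events`` (the
    detected-event table as flat columns) when provided.
    """
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["seed"] = -1 if bundle.seed is None else int(bundle.seed)
        acq = h5.create_group("acquisition")
        for trace in bundle.traces:
            ds = acq.create_dataset(f"trial_{trace.trial_index:03d}", data=trace.values)
            ds.attrs["sampling_rate_hz"] = trace.sampling_rate
            ds.attrs["modality"] = trace.modality
            if trace.capacitance is not None:
                ds.attrs["capacitance_pf"] = trace.capacitance
        vr = h5.create_group("ventral_root")
        for trace in bundle.ventral_root:
            ds = vr.create_dataset(f"trial_{trace.trial_index:03d}", data=trace.values)
            ds.attrs["sampling_rate_hz"] = trace.sampling_rate
        epochs = h5.create_group("epochs")
        for p in bundle.protocol:
            g = epochs.create_group(f"trial_{p.trial_index:03d}")
            for k, v in p.to_dict().items():
                if v is not None:
                    g.attrs[k] = v
        if events is not None and len(events):
            ev = h5.create_group("events")
            ev.create_dataset("time_s", data=events["time_s"].to_numpy(float))
            ev.create_dataset("trial_index", data=events["trial_index"].to_numpy(int))
            ev.create_dataset(
                "label", data=np.array(events["label"], dtype=h5py.string_dtype())
            )
            ev.create_dataset("conductance_ns", data=events["conductance_ns"].to_numpy(float))
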