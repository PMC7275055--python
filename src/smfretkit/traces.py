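"""Per-molecule intensity trace containers and plain-text / HDF5 I/O.

A :class:`Trace` holds the raw donor (Cy3B-like) and acceptor
(AlexaFluor-647-like) intensity series of one immobilised molecule; a
:class:`TraceSet` is an ordered collection sharing a frame clock.  The
on-disk schema is a long-form TSV table with columns
``molecule_id, frame, I_D, I_A`` (one row per molecule per frame), or the
equivalent HDF5 layout, so that simulated and movie-extracted traces are
interchangeable downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class Trace:
    """Donor/acceptor intensity time series of a single molecule.

    Parameters
    ----------
    molecule_id : int
        Identifier unique within the parent :class:`TraceSet`.
    time : ndarray
        Frame times in seconds; strictly increasing, uniformly spaced.
    donor, acceptor : ndarray
        Raw channel intensities (arbitrary units), same length as ``time``.
    condition : str, optional
        Experimental condition / preset label.
    injection_frame : int, optional
        Frame index at which reagents were injected (real-time experiments).
    donor_only : bool
        True when the molecule carries no (active) acceptor fluorophore.
    """

    molecule_id: int
    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    condition: Optional[str] = None
    injection_frame: Optional[int] = None
    donor_only: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise ValueError("time, donor and acceptor series must have equal length")
        if len(self.time) == 0:
            raise ValueError("empty trace")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("frame times must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def frame_interval(self) -> float:
        """Seconds per frame (integration time)."""
        if len(self.time) < 2:
            return float("nan")
        return float(self.time[1] - self.time[0])


@dataclass
class GroundTruth:
    """Generator-side labels for one simulated molecule.

    ``event_kind`` is one of ``transfer``, ``donor_bleach``,
    ``acceptor_bleach`` or ``none`` and refers to the *first* terminal
    event visible in the trace; ``event_frame`` is the first frame showing
    the post-event signal.
    """

    molecule_id: int
    initial_state: int
    state_path: np.ndarray
    event_kind: str
    event_frame: Optional[int]
    donor_only: bool

    def __post_init__(self) -> None:
        self.state_path = np.asarray(self.state_path, dtype=int)
        if self.event_frame is not None and not (
            0 <= self.event_frame < len(self.state_path)
        ):
            raise ValueError("event frame outside trace")

    @property
    def dynamic(self) -> bool:
        """True when the molecule visits more than one conformational state."""
        upto = self.event_frame if self.event_frame is not None else len(self.state_path)
        path = self.state_path[: max(upto, 1)]
        return bool(np.unique(path).size > 1)


class TraceSet:
    """Ordered collection of traces, optionally with simulation ground truth."""

    def __init__(
        self,
        traces: Sequence[Trace],
        ground_truth: Optional[Sequence[GroundTruth]] = None,
        metadata: Optional[dict] = None,
    ):
        self.traces = list(traces)
        self.ground_truth = list(ground_truth) if ground_truth is not None else None
        if self.ground_truth is not None and len(self.ground_truth) != len(self.traces):
            raise ValueError("ground truth must have one entry per trace")
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces)

    def __getitem__(self, i) -> Trace:
        return self.traces[i]

    # ------------------------------------------------------------------ #
    # tabular conversion
    # ------------------------------------------------------------------ #
    def to_frame(self) -> pd.DataFrame:
        """Long-form table: molecule_id, frame, time_s, I_D, I_A."""
        parts = []
        for tr in self.traces:
            parts.append(
                pd.DataFrame(
                    {
                        "molecule_id": tr.molecule_id,
                        "frame": np.arange(tr.n_frames),
                        "time_s": tr.time,
                        "I_D": tr.donor,
                        "I_A": tr.acceptor,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    def truth_frame(self) -> Optional[pd.DataFrame]:
        if self.ground_truth is None:
            return None
        return pd.DataFrame(
            {
                "molecule_id": [g.molecule_id for g in self.ground_truth],
                "initial_state": [g.initial_state for g in self.ground_truth],
                "event_kind": [g.event_kind for g in self.ground_truth],
                "event_frame": [
                    -1 if g.event_frame is None else g.event_frame
                    for g in self.ground_truth
                ],
                "donor_only": [g.donor_only for g in self.ground_truth],
                "dynamic": [g.dynamic for g in self.ground_truth],
            }
        )

    # ------------------------------------------------------------------ #
    # TSV I/O
    # ------------------------------------------------------------------ #
    def write_tsv(self, path, truth_path=None) -> None:
        path = Path(path)
        header = "".join(f"# {k}: {v}\n" for k, v in sorted(self.metadata.items()))
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, sep="\t", index=False)
        if truth_path is not None and self.ground_truth is not None:
            tf = self.truth_frame()
            with open(truth_path, "w") as fh:
                fh.write(header)
                tf.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, truth_path=None, **trace_kwargs) -> "TraceSet":
        path = Path(path)
        metadata = {}
        with open(path) as fh:
            while True:
                pos = fh.tell()
                line = fh.readline()
                if line.startswith("#"):
                    key, _, val = line[1:].partition(":")
                    metadata[key.strip()] = val.strip()
                else:
                    fh.seek(pos)
                    break
            df = pd.read_csv(fh, sep="\t")
        out = cls._from_frame(df, metadata, **trace_kwargs)
        traces = out.traces
        truth = None
        if truth_path is not None:
            tdf = pd.read_csv(truth_path, sep="\t", comment="#")
            truth = []
            by_id = {tr.molecule_id: tr for tr in traces}
            for _, row in tdf.iterrows():
                n = by_id[int(row["molecule_id"])].n_frames
                ef = int(row["event_frame"])
                truth.append(
                    GroundTruth(
                        molecule_id=int(row["molecule_id"]),
                        initial_state=int(row["initial_state"]),
                        state_path=np.full(n, int(row["initial_state"])),
                        event_kind=str(row["event_kind"]),
                        event_frame=None if ef < 0 else ef,
                        donor_only=bool(row["donor_only"]),
                    )
                )
        return cls(traces, ground_truth=truth, metadata=metadata)

    @classmethod
    def _from_frame(cls, df: pd.DataFrame, metadata: dict, **trace_kwargs) -> "TraceSet":
        required = {"molecule_id", "frame", "I_D", "I_A"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trace table missing columns: {sorted(missing)}")
        dt = float(metadata.get("frame_interval", trace_kwargs.pop("frame_interval", 1.0)))
        injection = metadata.get("injection_frame")
        injection = int(injection) if injection not in (None, "", "None") else None
        traces = []
        for mid, grp in df.groupby("molecule_id", sort=True):
            grp = grp.sort_values("frame")
            time = (
                grp["time_s"].to_numpy()
                if "time_s" in grp.columns
                else grp["frame"].to_numpy() * dt
            )
            traces.append(
                Trace(
                    molecule_id=int(mid),
                    time=np.asarray(time, dtype=float),
                    donor=grp["I_D"].to_numpy(),
                    acceptor=grp["I_A"].to_numpy(),
                    condition=metadata.get("condition"),
                    injection_frame=injection,
                    **trace_kwargs,
                )
            )
        return cls(traces, metadata=metadata)

    # ------------------------------------------------------------------ #
    # HDF5 I/O
    # ------------------------------------------------------------------ #
    def write_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for k, v in self.metadata.items():
                f.attrs[k] = v
            df = self.to_frame()
            for col in df.columns:
                f.create_dataset(col, data=df[col].to_numpy())
            if self.ground_truth is not None:
                g = f.create_group("ground_truth")
                tf = self.truth_frame()
                for col in tf.columns:
                    data = tf[col].to_numpy()
                    if data.dtype == object:
                        data = data.astype("S")
                    g.create_dataset(col, data=data)

    @classmethod
    def read_hdf5(cls, path) -> "TraceSet":
        import h5py

        with h5py.File(path, "r") as f:
            metadata = {k: str(f.attrs[k]) for k in f.attrs}
            df = pd.DataFrame(
                {
                    col: f[col][:]
                    for col in ("molecule_id", "frame", "time_s", "I_D", "I_A")
                    if col in f
                }
            )
        return cls._from_frame(df, metadata)

    def write_truth_json(self, path) -> None:
        if self.ground_truth is None:
            raise ValueError("trace set carries no ground truth")
        records = []
        for g in self.ground_truth:
            records.append(
                {
                    "molecule_id": g.molecule_id,
                    "initial_state": g.initial_state,
                    "event_kind": g.event_kind,
                    "event_frame": g.event_frame,
                    "donor_only": g.donor_only,
                    "dynamic": g.dynamic,
                }
            )
        Path(path).write_text(json.dumps(records, indent=1))
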