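"""Core FRET mathematics.

Apparent FRET efficiency is computed from raw donor and acceptor channel
intensities with a spectral-leakage correction factor alpha::

    E = I_A / (I_D + alpha * I_A)

where alpha = 0.88 compensates for 12% of donor emission bleeding into the
acceptor detection channel.  The module also provides the standard Förster
distance-efficiency relation E(r) = 1 / (1 + (r/R0)^6) and the population
histogram construction used to compare conditions: one sample per molecule,
the mean apparent E over the first ten valid frames, binned into a
unit-area density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .traces import Trace

DEFAULT_ALPHA = 0.88
DEFAULT_R0 = 60.0  # Angstrom, Cy3B / AlexaFluor 647
DEFAULT_BIN_RANGE = (-0.1, 1.1)
DEFAULT_N_BINS = 60


@dataclass
class FretParams:
    """Parameters of the apparent-efficiency calculation.

    alpha : donor-into-acceptor leakage correction factor (0 < alpha <= 1).
    clamp : when True, efficiencies are clipped to [0, 1]; off by default so
        that raw sub-zero / super-unity ratios remain visible in histograms.
    """

    alpha: float = DEFAULT_ALPHA
    clamp: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class FretTrajectory:
    """Per-frame apparent FRET efficiency with a validity mask.

    Frames can be invalid either because the denominator of the efficiency
    ratio is non-positive (no signal) or because they fall after a terminal
    event (photobleach or reaction) and were masked by the caller.
    """

    molecule_id: int
    time: np.ndarray
    efficiency: np.ndarray
    valid: np.ndarray
    condition: Optional[str] = None
    injection_frame: Optional[int] = None
    donor_only: bool = False

    def __post_init__(self) -> None:
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.efficiency) != len(self.valid) or len(self.time) != len(self.valid):
            raise ValueError("efficiency, validity mask and time must align")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def masked_after(self, frame: Optional[int]) -> "FretTrajectory":
        """Return a copy with all frames at/after ``frame`` marked invalid."""
        if frame is None:
            return self
        valid = self.valid.copy()
        valid[int(frame):] = False
        return FretTrajectory(
            self.molecule_id, self.time, self.efficiency, valid,
            condition=self.condition, injection_frame=self.injection_frame,
            donor_only=self.donor_only,
        )


def compute_fret_trajectory(trace: Trace, params: Optional[FretParams] = None) -> FretTrajectory:
    """Apparent FRET efficiency E = I_A / (I_D + alpha * I_A) per frame.

    Frames where the denominator is non-positive are masked invalid.  Raises
    ``ValueError`` when intensities are not finite and warns when every frame
    of the trace is invalid.
    """
    params = params or FretParams()
    d = trace.donor
    a = trace.acceptor
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(a))):
        raise ValueError("trace intensities must be finite")
    denom = d + params.alpha * a
    valid = denom > 0
    eff = np.full(len(d), np.nan)
    eff[valid] = a[valid] / denom[valid]
    if params.clamp:
        eff = np.clip(eff, 0.0, 1.0)
    if not valid.any():
        warnings.warn(
            f"molecule {trace.molecule_id}: all frames invalid (no signal)",
            RuntimeWarning,
        )
    return FretTrajectory(
        molecule_id=trace.molecule_id,
        time=trace.time,
        efficiency=eff,
        valid=valid,
        condition=trace.condition,
        injection_frame=trace.injection_frame,
        donor_only=trace.donor_only,
    )


# --------------------------------------------------------------------------- #
# Förster relation
# --------------------------------------------------------------------------- #
@dataclass
class ForsterModel:
    """Förster radius of the dye pair (Angstrom)."""

    R0: float = DEFAULT_R0

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")


def distance_to_efficiency(r, model: Optional[ForsterModel] = None) -> np.ndarray:
    """E(r) = 1 / (1 + (r/R0)^6); E(0) = 1, E(R0) = 0.5."""
    model = model or ForsterModel()
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("inter-dye distance must be non-negative")
    return 1.0 / (1.0 + (r / model.R0) ** 6)


def efficiency_to_distance(e, model: Optional[ForsterModel] = None) -> np.ndarray:
    """Inverse Förster relation, defined for E in (0, 1]."""
    model = model or ForsterModel()
    e = np.asarray(e, dtype=float)
    if np.any((e <= 0) | (e > 1)):
        raise ValueError("efficiency must lie in (0, 1]")
    return model.R0 * (1.0 / e - 1.0) ** (1.0 / 6.0)


# --------------------------------------------------------------------------- #
# Population histograms
# --------------------------------------------------------------------------- #
@dataclass
class FretHistogram:
    """Unit-area FRET population histogram.

    ``samples`` holds the per-molecule averaged efficiencies the densities
    were built from (one sample per molecule for population histograms; one
    sample per surviving frame for time-windowed histograms).
    """

    bin_edges: np.ndarray
    density: np.ndarray
    n_molecules: int
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.density) != len(self.bin_edges) - 1:
            raise ValueError("density must have one entry per bin")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def area(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))

    @property
    def empty(self) -> bool:
        return self.n_molecules == 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "density": self.density,
            }
        )


def _make_histogram(samples: np.ndarray, bins, bin_range) -> FretHistogram:
    samples = np.asarray(samples, dtype=float)
    if samples.size:
        density, edges = np.histogram(samples, bins=bins, range=bin_range, density=True)
    else:
        edges = np.histogram_bin_edges(np.empty(0), bins=bins, range=bin_range)
        density = np.zeros(len(edges) - 1)
    return FretHistogram(edges, density, n_molecules=samples.size, samples=samples)


def molecule_mean_efficiencies(
    trajectories: Sequence[FretTrajectory],
    n_init_frames: int = 10,
    min_valid_frames: int = 3,
) -> np.ndarray:
    """One averaged-E sample per molecule.

    Each sample is the mean apparent efficiency over the first
    ``n_init_frames`` valid frames of the trajectory; molecules with fewer
    valid frames contribute the mean over all they have, and molecules with
    fewer than ``min_valid_frames`` valid frames are dropped (their sample
    variance would dominate the histogram).
    """
    samples = []
    for traj in trajectories:
        e = traj.efficiency[traj.valid]
        if e.size < min_valid_frames:
            continue
        samples.append(float(np.mean(e[:n_init_frames])))
    return np.asarray(samples)


def build_population_histogram(
    trajectories: Sequence[FretTrajectory],
    n_init_frames: int = 10,
    bins: int = DEFAULT_N_BINS,
    bin_range: Tuple[float, float] = DEFAULT_BIN_RANGE,
    min_valid_frames: int = 3,
) -> FretHistogram:
    """First-ten-frame averaged population histogram, normalised to unit area."""
    samples = molecule_mean_efficiencies(trajectories, n_init_frames, min_valid_frames)
    if samples.size == 0:
        raise ValueError("no molecules with enough valid frames")
    return _make_histogram(samples, bins, bin_range)


def windowed_histograms(
    trajectories: Sequence[FretTrajectory],
    window_s: float = 15.0,
    bins: int = DEFAULT_N_BINS,
    bin_range: Tuple[float, float] = DEFAULT_BIN_RANGE,
    t_max: Optional[float] = None,
    normalise: bool = True,
) -> Tuple[List[FretHistogram], np.ndarray]:
    """Time-resolved FRET population: one histogram per time window.

    Only valid frames contribute (callers mask frames after each molecule's
    terminal event), so the row-to-row evolution of the returned matrix shows
    which states lose population as the reaction proceeds.  Returns the list
    of per-window histograms (empty windows flagged via ``empty``) and a 2-D
    matrix with one row per window and one column per FRET bin; rows are
    area-normalised when ``normalise`` is true, raw counts otherwise.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    dt = float(trajectories[0].time[1] - trajectories[0].time[0]) if len(trajectories[0].time) > 1 else window_s
    if window_s < dt:
        raise ValueError("window shorter than one frame")
    if t_max is None:
        t_max = max(float(tr.time[-1]) for tr in trajectories) + dt
    n_windows = int(np.ceil(round(t_max / window_s, 9)))
    edges = np.histogram_bin_edges(np.empty(0), bins=bins, range=bin_range)
    hists: List[FretHistogram] = []
    matrix = np.zeros((n_windows, len(edges) - 1))
    for w in range(n_windows):
        lo, hi = w * window_s, (w + 1) * window_s
        samples = []
        for traj in trajectories:
            sel = traj.valid & (traj.time >= lo) & (traj.time < hi)
            samples.append(traj.efficiency[sel])
        samples = np.concatenate(samples) if samples else np.empty(0)
        counts, _ = np.histogram(samples, bins=edges)
        if samples.size and normalise:
            matrix[w] = counts / (samples.size * np.diff(edges))
        else:
            matrix[w] = counts
        hists.append(_make_histogram(samples, edges, bin_range))
    return hists, matrix
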