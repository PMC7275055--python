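"""End-to-end analysis workflows and report bundling.

Two workflows mirror the two experiment types:

* :func:`equilibrium_analysis` — population histogram of first-ten-frame
  averaged efficiencies, Gaussian-mixture decomposition into low /
  intermediate / high FRET states with fractional occupancies, per-trace
  donor-acceptor cross-correlation, and interconversion statistics.
* :func:`realtime_analysis` — per-molecule event classification after
  reagent injection, reacted fractions, dwell-time exponential fits per
  event class, per-initial-state reaction rates, the time-windowed FRET
  population matrix and cumulative intensity curves.

Every emitted file carries a provenance header (configuration hash and
seed) so identical runs are reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np

from .fret import (
    FretParams,
    build_population_histogram,
    compute_fret_trajectory,
    windowed_histograms,
)
from .kinetics import (
    StepThresholds,
    classify_events,
    cross_correlation,
    detect_interconversion,
    dwell_histogram_fit,
    per_state_reaction_rates,
    reacted_fractions,
    cumulative_intensity,
)
from .populations import fit_gaussian_mixture, population_fractions
from .traces import TraceSet


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    return hashlib.sha1(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def provenance(seed: int, config: dict) -> dict:
    return {"seed": seed, "config_hash": config_hash(config)}


def masked_trajectories(traceset: TraceSet, params: FretParams, thresholds=None):
    """FRET trajectories with frames after each molecule's terminal event
    masked out, using the event classifier (not ground truth)."""
    events = classify_events(traceset, thresholds=thresholds, fret_params=params)
    trajectories = []
    for tr, ev in zip(traceset, events):
        traj = compute_fret_trajectory(tr, params).masked_after(ev.event_frame)
        trajectories.append(traj)
    return trajectories, events


def equilibrium_analysis(
    traceset: TraceSet,
    fret_params: Optional[FretParams] = None,
    k: Optional[int] = 3,
    k_range: Sequence[int] = (1, 2, 3),
    n_init_frames: int = 10,
    bins: int = 60,
    seed: int = 0,
    max_lag: int = 50,
    thresholds: Optional[StepThresholds] = None,
    compute_crosscorr: bool = True,
) -> dict:
    """Full equilibrium-experiment analysis of a trace set.

    Returns a dict with the unit-area histogram, the Gaussian-mixture fit,
    per-state fractional occupancies, the interconversion (dynamic) fraction
    and a cross-correlation summary over molecules.
    """
    if len(traceset) == 0:
        raise ValueError("empty trace set")
    params = fret_params or FretParams()
    trajectories, events = masked_trajectories(traceset, params, thresholds)
    hist = build_population_histogram(trajectories, n_init_frames=n_init_frames, bins=bins)
    fit = fit_gaussian_mixture(hist.samples, k=k, k_range=k_range, seed=seed)
    fractions = population_fractions(fit)
    n_dyn = 0
    for traj, ev in zip(trajectories, events):
        dynamic, _ = detect_interconversion(traj, fit)
        n_dyn += dynamic
    xcorr = None
    if compute_crosscorr:
        g0 = []
        for tr, ev in zip(traceset, events):
            stop = ev.event_frame if ev.event_frame is not None else tr.n_frames
            if stop <= max_lag + 1:
                continue
            sub = type(tr)(
                molecule_id=tr.molecule_id,
                time=tr.time[:stop],
                donor=tr.donor[:stop],
                acceptor=tr.acceptor[:stop],
            )
            g0.append(cross_correlation(sub, max_lag).g)
        if g0:
            g = np.mean(g0, axis=0)
            xcorr = {
                "lags_frames": list(range(max_lag + 1)),
                "mean_g": g.tolist(),
                "g0_mean": float(g[0]),
                "n_traces": len(g0),
            }
    return {
        "n_molecules": len(traceset),
        "histogram": hist,
        "mixture_fit": fit,
        "fractions": fractions,
        "fractions_percent": {k_: 100.0 * v for k_, v in fractions.items()},
        "dynamic_fraction_percent": 100.0 * n_dyn / len(traceset),
        "cross_correlation": xcorr,
        "events": events,
    }


def realtime_analysis(
    traceset: TraceSet,
    fret_params: Optional[FretParams] = None,
    thresholds: Optional[StepThresholds] = None,
    window_s: float = 15.0,
    bins: int = 60,
    dwell_model: str = "auto",
) -> dict:
    """Full real-time (injection) experiment analysis of a trace set."""
    if len(traceset) == 0:
        raise ValueError("empty trace set")
    injection = traceset.traces[0].injection_frame
    if injection is None:
        raise ValueError("real-time analysis requires an injection frame")
    params = fret_params or FretParams()
    events = classify_events(traceset, thresholds=thresholds, fret_params=params)
    fractions = reacted_fractions(events)
    dt = traceset.traces[0].frame_interval

    dwell_fits: Dict[str, dict] = {}
    for cls in ("transfer_FRET", "transfer_donor_only", "acceptor_photobleach", "donor_photobleach"):
        dwells = [e.dwell_s for e in events if e.kind == cls and not e.excluded and e.dwell_s]
        if len(dwells) >= 10:
            fit = dwell_histogram_fit(dwells, model=dwell_model, frame_interval=dt)
            dwell_fits[cls] = fit.to_dict()
        else:
            dwell_fits[cls] = {"n_events": len(dwells), "warning": "too few events to fit"}

    per_state = per_state_reaction_rates(events)

    trajectories = []
    for tr, ev in zip(traceset, events):
        traj = compute_fret_trajectory(tr, params).masked_after(ev.event_frame)
        trajectories.append(traj)
    hists, matrix = windowed_histograms(trajectories, window_s=window_s, bins=bins)
    cum = cumulative_intensity(traceset)
    return {
        "n_molecules": len(traceset),
        "injection_frame": injection,
        "events": events,
        "reacted_fractions_percent": fractions,
        "dwell_fits": dwell_fits,
        "per_state_rates": per_state,
        "window_edges_s": [window_s * i for i in range(matrix.shape[0] + 1)],
        "population_matrix": matrix,
        "windowed_histograms": hists,
        "cumulative_intensity": cum,
    }


# --------------------------------------------------------------------------- #
# Report writing
# --------------------------------------------------------------------------- #
def _header_lines(prov: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in sorted(prov.items()))


def write_events_tsv(path, events, prov: dict) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "molecule_id": [e.molecule_id for e in events],
            "class": [e.kind for e in events],
            "event_frame": [-1 if e.event_frame is None else e.event_frame for e in events],
            "dwell_s": [np.nan if e.dwell_s is None else e.dwell_s for e in events],
            "initial_state": [e.initial_state or "" for e in events],
            "donor_only": [e.donor_only for e in events],
            "excluded": [e.excluded for e in events],
        }
    )
    with open(path, "w") as fh:
        fh.write(_header_lines(prov))
        df.to_csv(fh, sep="\t", index=False)


def write_matrix_tsv(path, matrix: np.ndarray, prov: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(prov))
        np.savetxt(fh, matrix, delimiter="\t", fmt="%.6g")


def write_histogram_tsv(path, hist, prov: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(prov))
        hist.to_frame().to_csv(fh, sep="\t", index=False)


def write_equilibrium_report(outdir, report: dict, prov: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_histogram_tsv(outdir / "histogram.tsv", report["histogram"], prov)
    summary = {
        "provenance": prov,
        "n_molecules": report["n_molecules"],
        "mixture_fit": report["mixture_fit"].to_dict(),
        "fractions_percent": report["fractions_percent"],
        "dynamic_fraction_percent": report["dynamic_fraction_percent"],
        "cross_correlation": report["cross_correlation"],
    }
    (outdir / "equilibrium.json").write_text(json.dumps(summary, indent=1))


def write_realtime_report(outdir, report: dict, prov: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_events_tsv(outdir / "events.tsv", report["events"], prov)
    write_matrix_tsv(outdir / "population_matrix.tsv", report["population_matrix"], prov)
    per_state = {
        k: {kk: vv for kk, vv in v.items() if kk != "rates_per_s"}
        for k, v in report["per_state_rates"].items()
    }
    summary = {
        "provenance": prov,
        "n_molecules": report["n_molecules"],
        "injection_frame": report["injection_frame"],
        "reacted_fractions_percent": report["reacted_fractions_percent"],
        "dwell_fits": report["dwell_fits"],
        "per_state_rates": per_state,
    }
    (outdir / "realtime.json").write_text(json.dumps(summary, indent=1))


def bundle_report(outdir) -> dict:
    """Combine any equilibrium/realtime JSON summaries under ``outdir``
    into a single ``report.json``."""
    outdir = Path(outdir)
    combined = {}
    for name in ("equilibrium.json", "realtime.json"):
        p = outdir / name
        if p.exists():
            combined[name.split(".")[0]] = json.loads(p.read_text())
    (outdir / "report.json").write_text(json.dumps(combined, indent=1))
    return combined
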