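"""Trajectory dynamics and single-turnover reaction kinetics.

Covers donor-acceptor cross-correlation, detection of rare interconversion
between FRET states, per-molecule classification of real-time reaction
events, reacted-fraction summaries, dwell-time exponential fits and
per-initial-state reaction rates, and population-level cumulative
intensity curves.

Event signatures
----------------
``transfer_FRET``
    simultaneous (within one frame) irreversible loss of both channels:
    the dye-carrying ubiquitin leaves the surface-tethered conjugate.
``acceptor_photobleach``
    acceptor falls to background while the donor *recovers* (energy
    transfer stops, so donor emission rises to the full excitation level).
``donor_photobleach``
    donor falls with the acceptor already dark and no earlier
    acceptor-bleach signature.
``transfer_donor_only``
    loss of donor signal from a molecule that never showed acceptor signal.
``unreacted``
    both channels persist to the end of the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit, minimize

from .fret import FretParams, FretTrajectory, compute_fret_trajectory
from .populations import GaussianMixtureFit, STATE_LABELS, assign_states
from .simulate import DEFAULT_STATE_MEANS
from .traces import Trace, TraceSet

EVENT_CLASSES = (
    "transfer_FRET",
    "transfer_donor_only",
    "acceptor_photobleach",
    "donor_photobleach",
    "unreacted",
    "ambiguous",
)


# --------------------------------------------------------------------------- #
# Cross-correlation
# --------------------------------------------------------------------------- #
@dataclass
class CrossCorrelation:
    """Donor-acceptor intensity cross-correlation G(tau)."""

    lags_frames: np.ndarray
    lags_s: np.ndarray
    g: np.ndarray
    n: int
    mean_donor: float
    mean_acceptor: float


def cross_correlation(
    trace: Trace,
    max_lag: int,
    denominator: str = "mean_of_products",
) -> CrossCorrelation:
    """G(tau) = sum_t (I_D(t) - mean_D)(I_A(t+tau) - mean_A) / (N * norm).

    ``norm`` is the mean of the per-frame products I_D(t)*I_A(t) by default
    (``mean_of_products``) or the product of the channel means
    (``product_of_means``).  Channel means are taken over the full
    trajectory.  Anticorrelated switching between FRET states yields
    G(0) < 0; static traces fluctuate around zero.
    """
    n = trace.n_frames
    if not 0 <= max_lag < n:
        raise ValueError("require 0 <= max_lag < trace length")
    d = trace.donor
    a = trace.acceptor
    md, ma = float(np.mean(d)), float(np.mean(a))
    if denominator == "mean_of_products":
        norm = float(np.mean(d * a))
    elif denominator == "product_of_means":
        norm = md * ma
    else:
        raise ValueError("denominator must be 'mean_of_products' or 'product_of_means'")
    if norm == 0.0:
        raise ZeroDivisionError("cross-correlation denominator is zero")
    dd = d - md
    da = a - ma
    g = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        g[tau] = np.sum(dd[: n - tau] * da[tau:]) / (n * norm)
    lags = np.arange(max_lag + 1)
    return CrossCorrelation(
        lags_frames=lags,
        lags_s=lags * trace.frame_interval if n > 1 else lags.astype(float),
        g=g,
        n=n,
        mean_donor=md,
        mean_acceptor=ma,
    )


# --------------------------------------------------------------------------- #
# Interconversion detection
# --------------------------------------------------------------------------- #
def detect_interconversion(
    trajectory: FretTrajectory,
    fit: GaussianMixtureFit,
    event_frame: Optional[int] = None,
    min_dwell_frames: int = 3,
) -> Tuple[bool, List[Tuple[int, int, int]]]:
    """Flag trajectories that switch FRET state before any terminal event.

    Returns ``(dynamic, transitions)`` where each transition is
    ``(frame, from_state, to_state)`` in component indices of ``fit``.
    """
    traj = trajectory.masked_after(event_frame)
    labels = assign_states(traj, fit, min_dwell_frames=min_dwell_frames)
    valid = np.flatnonzero(labels >= 0)
    transitions: List[Tuple[int, int, int]] = []
    if valid.size >= 2:
        lv = labels[valid]
        steps = np.flatnonzero(np.diff(lv) != 0)
        for s in steps:
            transitions.append((int(valid[s + 1]), int(lv[s]), int(lv[s + 1])))
    return bool(transitions), transitions


# --------------------------------------------------------------------------- #
# Real-time event classification
# --------------------------------------------------------------------------- #
@dataclass
class StepThresholds:
    """Parameters of the per-channel step detector.

    ``background`` is the dark-channel level; ``sigma`` the per-channel
    noise s.d. (estimated robustly from the trace when None).  A channel is
    considered lost when it stays below ``background + drop_sd * sigma`` for
    at least ``sustain_frames`` frames, and must not rise back above
    threshold for ``recovery_frames`` consecutive frames afterwards.
    ``sync_frames`` defines "simultaneous" loss of the two channels (one
    frame at the 1-s real-time integration time).
    """

    background: float = 0.0
    sigma: Optional[float] = None
    drop_sd: float = 3.0
    sustain_frames: int = 3
    recovery_frames: int = 3
    sync_frames: int = 1
    donor_only_window: int = 5


@dataclass
class EventCall:
    """Per-molecule classification of a real-time trace."""

    molecule_id: int
    kind: str
    event_frame: Optional[int]
    dwell_s: Optional[float]
    initial_state: Optional[str]
    donor_only: bool
    excluded: bool = False  # event during the injection interval


def _robust_sigma(x: np.ndarray) -> float:
    """Noise s.d. from the median absolute first difference."""
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _first_sustained_drop(x: np.ndarray, thr: float, sustain: int) -> Optional[int]:
    """First frame where ``x`` falls below ``thr`` for >= ``sustain`` frames,
    having been above threshold immediately before."""
    n = len(x)
    if n < sustain + 1:
        return None
    below = x < thr
    windows = np.lib.stride_tricks.sliding_window_view(below, sustain)
    sustained = windows.all(axis=1)
    for f in np.flatnonzero(sustained):
        if f == 0:
            continue
        pre = x[max(0, f - 5): f]
        if np.mean(pre) > thr:
            return int(f)
    return None


def _recovers(x: np.ndarray, start: int, thr: float, recovery_frames: int) -> bool:
    """True when the channel rises back above threshold for a sustained run."""
    seg = x[start:] >= thr
    if seg.size < recovery_frames:
        return False
    windows = np.lib.stride_tricks.sliding_window_view(seg, recovery_frames)
    return bool(windows.all(axis=1).any())


def _initial_state_label(
    trace: Trace,
    event_frame: Optional[int],
    params: FretParams,
    state_means: Sequence[float],
    state_labels: Sequence[str],
    n_frames: int = 10,
) -> Optional[str]:
    traj = compute_fret_trajectory(trace, params)
    stop = event_frame if event_frame is not None else trace.n_frames
    e = traj.efficiency[:stop][traj.valid[:stop]][:n_frames]
    if e.size == 0:
        return None
    m = float(np.mean(e))
    idx = int(np.argmin(np.abs(np.asarray(state_means) - m)))
    return list(state_labels)[idx]


def classify_event(
    trace: Trace,
    injection_frame: Optional[int] = None,
    thresholds: Optional[StepThresholds] = None,
    state_means: Sequence[float] = DEFAULT_STATE_MEANS,
    state_labels: Sequence[str] = STATE_LABELS,
    fret_params: Optional[FretParams] = None,
) -> EventCall:
    """Classify a single real-time trace into an :class:`EventCall`.

    Equilibrium traces use ``injection_frame=0`` so that every terminal
    event carries a dwell time.  Events that fall within the injection
    interval are classified but marked ``excluded`` (no dwell) so they do
    not enter rate fits.
    """
    thr = thresholds or StepThresholds()
    params = fret_params or FretParams()
    if injection_frame is None:
        injection_frame = trace.injection_frame if trace.injection_frame is not None else 0
    d, a = trace.donor, trace.acceptor
    sig_d = thr.sigma if thr.sigma is not None else _robust_sigma(d)
    sig_a = thr.sigma if thr.sigma is not None else _robust_sigma(a)
    # epsilon keeps the detector functional on noise-free traces, where the
    # post-event level equals the background exactly
    eps = 1e-9 * (max(np.max(np.abs(d)), np.max(np.abs(a))) + 1.0)
    thr_d = thr.background + thr.drop_sd * sig_d + eps
    thr_a = thr.background + thr.drop_sd * sig_a + eps

    w = min(thr.donor_only_window, trace.n_frames)
    donor_only = bool(np.mean(a[:w]) < thr_a)

    f_d = _first_sustained_drop(d, thr_d, thr.sustain_frames)
    f_a = None if donor_only else _first_sustained_drop(a, thr_a, thr.sustain_frames)

    kind: str
    event_frame: Optional[int]
    if donor_only:
        if f_d is None:
            kind, event_frame = "unreacted", None
        elif _recovers(d, f_d, thr_d, thr.recovery_frames):
            kind, event_frame = "ambiguous", f_d
        else:
            kind, event_frame = "transfer_donor_only", f_d
    elif f_d is None and f_a is None:
        kind, event_frame = "unreacted", None
    elif f_d is not None and f_a is not None and abs(f_d - f_a) <= thr.sync_frames:
        # simultaneous dual loss; transfer must show no recovery of either
        f = max(f_d, f_a)
        if _recovers(d, f, thr_d, thr.recovery_frames) or _recovers(
            a, f, thr_a, thr.recovery_frames
        ):
            kind, event_frame = "ambiguous", f
        else:
            kind, event_frame = "transfer_FRET", f
    elif f_a is not None and (f_d is None or f_d > f_a + thr.sync_frames):
        # acceptor lost first: photobleach shows concomitant donor recovery
        pre = d[max(0, f_a - 5): f_a]
        post = d[f_a: f_a + 5]
        if post.size and pre.size and np.mean(post) > np.mean(pre) + thr.drop_sd * sig_d / np.sqrt(post.size):
            kind, event_frame = "acceptor_photobleach", f_a
        else:
            kind, event_frame = "ambiguous", f_a
    else:
        # donor lost while acceptor persisted: no FRET signature matches
        pre_a = a[:f_d] if f_d else a[:1]
        if np.mean(pre_a) < thr_a:
            kind, event_frame = "donor_photobleach", f_d
        else:
            kind, event_frame = "ambiguous", f_d

    dt = trace.frame_interval
    excluded = event_frame is not None and event_frame <= injection_frame
    dwell = None
    if event_frame is not None and not excluded and np.isfinite(dt):
        dwell = float((event_frame - injection_frame) * dt)
    initial = _initial_state_label(
        trace, event_frame, params, state_means, state_labels
    ) if not donor_only else None
    return EventCall(
        molecule_id=trace.molecule_id,
        kind=kind,
        event_frame=event_frame,
        dwell_s=dwell,
        initial_state=initial,
        donor_only=donor_only,
        excluded=excluded,
    )


def classify_events(
    traceset: TraceSet,
    injection_frame: Optional[int] = None,
    thresholds: Optional[StepThresholds] = None,
    **kwargs,
) -> List[EventCall]:
    return [
        classify_event(tr, injection_frame=injection_frame, thresholds=thresholds, **kwargs)
        for tr in traceset
    ]


def reacted_fractions(events: Sequence[EventCall]) -> Dict[str, float]:
    """Percentage of molecules per event class.

    Reports every class plus ``transfer_combined`` (FRET-loss and donor-only
    transfer events together), over all classified molecules.
    """
    if not events:
        raise ValueError("no event calls")
    n = len(events)
    out = {}
    for cls in EVENT_CLASSES:
        out[cls] = 100.0 * sum(e.kind == cls for e in events) / n
    out["transfer_combined"] = out["transfer_FRET"] + out["transfer_donor_only"]
    out["n_molecules"] = n
    return out


# --------------------------------------------------------------------------- #
# Dwell-time kinetics
# --------------------------------------------------------------------------- #
@dataclass
class DwellFit:
    """Mono- or biexponential fit of a dwell-time distribution.

    ``rates``/``rate_se``/``amplitudes`` come from the weighted binned
    least-squares fit; ``mle_rates`` (and ``mle_weights`` for the
    biexponential) from the unbinned maximum-likelihood cross-check.  The
    AIC values are computed from the unbinned likelihoods.
    """

    model: str
    rates: np.ndarray
    rate_se: np.ndarray
    amplitudes: np.ndarray
    mle_rates: np.ndarray
    mle_weights: np.ndarray
    aic_mono: float
    aic_bi: float
    n_events: int
    fit_statistic: float
    warning: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "rates_per_s": np.asarray(self.rates).tolist(),
            "rate_se_per_s": np.asarray(self.rate_se).tolist(),
            "amplitudes": np.asarray(self.amplitudes).tolist(),
            "mle_rates_per_s": np.asarray(self.mle_rates).tolist(),
            "mle_weights": np.asarray(self.mle_weights).tolist(),
            "aic_mono": self.aic_mono,
            "aic_bi": self.aic_bi,
            "n_events": self.n_events,
            "fit_statistic": self.fit_statistic,
            "warning": self.warning,
        }


def _mono_loglik(dwells: np.ndarray) -> Tuple[float, float]:
    k = 1.0 / float(np.mean(dwells))
    ll = len(dwells) * np.log(k) - k * float(np.sum(dwells))
    return k, ll


def _bi_mle(dwells: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Two-component exponential mixture MLE via Nelder-Mead on
    (logit weight, log k1, log k2)."""
    mean = float(np.mean(dwells))

    def nll(p):
        w = 1.0 / (1.0 + np.exp(-p[0]))
        k1, k2 = np.exp(p[1]), np.exp(p[2])
        pdf = w * k1 * np.exp(-k1 * dwells) + (1 - w) * k2 * np.exp(-k2 * dwells)
        return -float(np.sum(np.log(np.maximum(pdf, 1e-300))))

    x0 = np.array([0.0, np.log(3.0 / mean), np.log(0.3 / mean)])
    res = minimize(nll, x0, method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    w = 1.0 / (1.0 + np.exp(-res.x[0]))
    ks = np.exp(res.x[1:3])
    order = np.argsort(ks)[::-1]  # fast component first
    weights = np.asarray([w, 1 - w])[order]
    return ks[order], weights, -res.fun


def dwell_histogram_fit(
    dwells: Sequence[float],
    model: str = "auto",
    frame_interval: float = 1.0,
    bin_width_s: Optional[float] = None,
) -> DwellFit:
    """Exponential fit of a dwell-time histogram.

    Dwell times are binned (bin width two frames by default) and the decay
    ``A exp(-k t)`` — or the two-term sum — is fitted by nonlinear least
    squares with sqrt(count) weights; standard errors come from the fit
    covariance.  An unbinned maximum-likelihood estimate is computed
    alongside, and when ``model="auto"`` the mono/biexponential choice is
    made by AIC.
    """
    dwells = np.asarray(dwells, dtype=float)
    dwells = dwells[np.isfinite(dwells) & (dwells > 0)]
    if dwells.size < 10:
        raise ValueError("need at least 10 dwell times")
    if model not in ("mono", "bi", "auto"):
        raise ValueError("model must be 'mono', 'bi' or 'auto'")

    k_mle, ll_mono = _mono_loglik(dwells)
    aic_mono = 2 * 1 - 2 * ll_mono

    if np.std(dwells) == 0.0:
        # degenerate: identical dwells carry no shape information
        msg = "identical dwell times; returning k = 1/mean without a fit"
        warnings.warn(msg, RuntimeWarning)
        return DwellFit(
            model="mono",
            rates=np.asarray([k_mle]),
            rate_se=np.asarray([np.nan]),
            amplitudes=np.asarray([float(dwells.size)]),
            mle_rates=np.asarray([k_mle]),
            mle_weights=np.asarray([1.0]),
            aic_mono=float(aic_mono),
            aic_bi=float("nan"),
            n_events=int(dwells.size),
            fit_statistic=float("nan"),
            warning=msg,
        )

    ks_bi, w_bi, ll_bi = _bi_mle(dwells)
    aic_bi = 2 * 3 - 2 * ll_bi
    if model == "auto":
        model = "bi" if aic_bi < aic_mono else "mono"

    width = bin_width_s if bin_width_s is not None else 2.0 * frame_interval
    edges = np.arange(0.0, dwells.max() + 2 * width, width)
    counts, _ = np.histogram(dwells, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    t, y = centers, counts.astype(float)
    # Zero-count bins stay in the fit (dropping them biases the rate high).
    # Poisson weights start from the observed counts and are iteratively
    # reweighted by the model prediction: weighting by observed counts alone
    # systematically steepens the decay at modest sample sizes.
    sigma = np.sqrt(np.maximum(y, 1.0))

    if model == "mono":
        def f(t, A, k):
            return A * np.exp(-k * t)

        p0 = [float(y.max()), k_mle]
        bounds = ([0.0, 1e-12], [np.inf, np.inf])
    else:
        def f(t, A1, k1, A2, k2):
            return A1 * np.exp(-k1 * t) + A2 * np.exp(-k2 * t)

        p0 = [float(y.max()) * w_bi[0], ks_bi[0], float(y.max()) * w_bi[1], ks_bi[1]]
        bounds = ([0.0, 1e-12, 0.0, 1e-12], [np.inf, np.inf, np.inf, np.inf])

    popt, pcov = curve_fit(
        f, t, y, p0=p0, sigma=sigma, absolute_sigma=True, bounds=bounds, maxfev=20000
    )
    for _ in range(3):
        sigma = np.sqrt(np.maximum(f(t, *popt), 0.25))
        popt, pcov = curve_fit(
            f, t, y, p0=popt, sigma=sigma, absolute_sigma=True, bounds=bounds, maxfev=20000
        )
    perr = np.sqrt(np.diag(pcov))
    resid = (y - f(t, *popt)) / sigma
    if model == "mono":
        rates = np.asarray([popt[1]])
        rate_se = np.asarray([perr[1]])
        amps = np.asarray([popt[0]])
        mle_rates = np.asarray([k_mle])
        mle_weights = np.asarray([1.0])
    else:
        order = np.argsort([popt[1], popt[3]])[::-1]
        rates = np.asarray([popt[1], popt[3]])[order]
        rate_se = np.asarray([perr[1], perr[3]])[order]
        amps = np.asarray([popt[0], popt[2]])[order]
        mle_rates = ks_bi
        mle_weights = w_bi
    return DwellFit(
        model=model,
        rates=rates,
        rate_se=rate_se,
        amplitudes=amps,
        mle_rates=mle_rates,
        mle_weights=mle_weights,
        aic_mono=float(aic_mono),
        aic_bi=float(aic_bi),
        n_events=int(dwells.size),
        fit_statistic=float(np.sum(resid**2)),
    )


# --------------------------------------------------------------------------- #
# Per-state reaction rates and cumulative intensity
# --------------------------------------------------------------------------- #
def per_state_reaction_rates(
    events: Sequence[EventCall],
    state_labels: Sequence[str] = STATE_LABELS,
) -> Dict[str, dict]:
    """Group per-molecule transfer rates (1/dwell) by initial FRET state.

    Returns, per state, the rate distribution summary (median, quartiles,
    extremes, n) and a group exponential rate estimate (1/mean dwell); a
    state with no transfer events is reported empty.
    """
    out: Dict[str, dict] = {}
    for lab in state_labels:
        dwells = np.asarray(
            [
                e.dwell_s
                for e in events
                if e.kind == "transfer_FRET"
                and not e.excluded
                and e.dwell_s
                and e.initial_state == lab
            ]
        )
        if dwells.size == 0:
            out[lab] = {"n": 0}
            continue
        rates = 1.0 / dwells
        q1, med, q3 = np.percentile(rates, [25, 50, 75])
        out[lab] = {
            "n": int(dwells.size),
            "median_rate_per_s": float(med),
            "q1_rate_per_s": float(q1),
            "q3_rate_per_s": float(q3),
            "min_rate_per_s": float(rates.min()),
            "max_rate_per_s": float(rates.max()),
            "group_rate_per_s": float(1.0 / np.mean(dwells)),
            "rates_per_s": rates.tolist(),
        }
    return out


def cumulative_intensity(
    traceset: TraceSet, normalise: bool = False
) -> Dict[str, np.ndarray]:
    """Total donor, acceptor and summed intensity over all molecules vs time.

    With ``normalise=True`` each curve is divided by its mean over the
    pre-injection frames (or the first 10 frames when no injection is set).
    """
    if len(traceset) == 0:
        raise ValueError("empty trace set")
    n = traceset.traces[0].n_frames
    if any(tr.n_frames != n for tr in traceset):
        raise ValueError("all traces must share a frame clock")
    donor = np.sum([tr.donor for tr in traceset], axis=0)
    acceptor = np.sum([tr.acceptor for tr in traceset], axis=0)
    total = donor + acceptor
    time = traceset.traces[0].time
    if normalise:
        inj = traceset.traces[0].injection_frame
        upto = inj if inj else min(10, n)
        for arr in (donor, acceptor, total):
            ref = np.mean(arr[:upto])
            if ref != 0:
                arr /= ref
    return {"time_s": time, "donor": donor, "acceptor": acceptor, "total": total}
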