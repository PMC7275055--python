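"""FRET state populations: Gaussian mixture decomposition and state labels.

The per-molecule averaged-efficiency population is decomposed into up to
three Gaussian components corresponding to the open (low-FRET),
intermediate and closed (high-FRET) conformations.  Two routes are
provided: expectation-maximisation on the samples themselves (default,
via scikit-learn) and least-squares fitting of a sum of Gaussians to the
unit-area histogram; on well-sampled synthetic data the two agree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

from .fret import FretHistogram, FretTrajectory

STATE_LABELS = ("low", "intermediate", "high")
#: Canonical apparent-efficiency positions of the three conformational states,
#: used to map fitted components onto state labels when fewer than three
#: components are selected.
REFERENCE_MEANS = {"low": 0.36, "intermediate": 0.57, "high": 0.71}
SD_FLOOR = 0.01


@dataclass
class GaussianMixtureFit:
    """K-component Gaussian mixture over a FRET population.

    Components are stored sorted by ascending mean (low -> high FRET).
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    bic: float
    converged: bool
    n_samples: int
    responsibilities: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if np.any(self.sds < SD_FLOOR - 1e-12):
            raise ValueError("component sd below configured floor")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("components must be sorted by ascending mean")

    @property
    def k(self) -> int:
        return len(self.means)

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for m, s, w in zip(self.means, self.sds, self.weights):
            out += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        return out

    def predict(self, x) -> np.ndarray:
        """Maximum-responsibility component index per sample."""
        x = np.asarray(x, dtype=float)[:, None]
        log_comp = (
            np.log(self.weights)
            - np.log(self.sds)
            - 0.5 * ((x - self.means) / self.sds) ** 2
        )
        return np.argmax(log_comp, axis=1)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "converged": self.converged,
            "n_samples": self.n_samples,
        }

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _fit_k(samples: np.ndarray, k: int, seed: int, n_init: int, tol: float) -> GaussianMixture:
    # k-means++ restarts are deterministic for a fixed random_state
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=n_init,
        tol=tol,
        reg_covar=SD_FLOOR**2,
        max_iter=500,
        random_state=seed,
        init_params="k-means++",
    )
    gm.fit(samples[:, None])
    return gm


def fit_gaussian_mixture(
    samples: Sequence[float],
    k_range: Sequence[int] = (1, 2, 3),
    k: Optional[int] = None,
    seed: int = 0,
    n_init: int = 20,
    tol: float = 1e-6,
    store_responsibilities: bool = False,
) -> GaussianMixtureFit:
    """EM Gaussian-mixture fit of a FRET sample population.

    Fits every k in ``k_range`` (or a fixed ``k``) with multiple restarts
    and returns the best model by BIC.  Deterministic for a given seed.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if samples.size < 20:
        raise ValueError("need at least 20 samples for a mixture fit")
    ks = [int(k)] if k is not None else sorted(int(x) for x in k_range)
    best, best_bic = None, np.inf
    for kk in ks:
        gm = _fit_k(samples, kk, seed, n_init, tol)
        bic = gm.bic(samples[:, None])
        if bic < best_bic:
            best, best_bic = gm, bic
    order = np.argsort(best.means_.ravel())
    resp = best.predict_proba(samples[:, None])[:, order] if store_responsibilities else None
    return GaussianMixtureFit(
        means=best.means_.ravel()[order],
        sds=np.sqrt(best.covariances_.ravel()[order]),
        weights=best.weights_[order],
        log_likelihood=float(best.score(samples[:, None]) * samples.size),
        bic=float(best_bic),
        converged=bool(best.converged_),
        n_samples=int(samples.size),
        responsibilities=resp,
    )


def fit_gaussians_to_histogram(
    hist: FretHistogram,
    k: int = 3,
    seed: int = 0,
) -> GaussianMixtureFit:
    """Least-squares fit of a sum of Gaussians to a unit-area histogram.

    This mirrors the common practice of fitting the binned population rather
    than the samples; on well-sampled data it agrees with the EM route.
    """
    x = hist.bin_centers
    y = hist.density

    def model(x, *p):
        out = np.zeros_like(x)
        for i in range(k):
            a, m, s = p[3 * i: 3 * i + 3]
            out += a * np.exp(-0.5 * ((x - m) / s) ** 2)
        return out

    qs = np.quantile(hist.samples, np.linspace(0.15, 0.85, k)) if hist.samples.size else np.linspace(0.3, 0.8, k)
    p0 = []
    for i in range(k):
        p0 += [float(y.max()) / k, float(qs[i]), 0.05]
    lb = [0.0, x[0], SD_FLOOR] * k
    ub = [np.inf, x[-1], (x[-1] - x[0])] * k
    popt, _ = curve_fit(model, x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    amps = popt[0::3]
    means = popt[1::3]
    sds = popt[2::3]
    # convert amplitudes to mixture weights (area of each component)
    areas = amps * sds * np.sqrt(2 * np.pi)
    weights = areas / areas.sum()
    order = np.argsort(means)
    resid = y - model(x, *popt)
    return GaussianMixtureFit(
        means=means[order],
        sds=np.maximum(sds[order], SD_FLOOR),
        weights=weights[order],
        log_likelihood=float(-0.5 * np.sum(resid**2)),
        bic=float(np.nan),
        converged=True,
        n_samples=hist.n_molecules,
    )


def population_fractions(
    fit: GaussianMixtureFit,
    state_labels: Sequence[str] = STATE_LABELS,
    reference_means: Optional[Dict[str, float]] = None,
) -> Dict[str, float]:
    """Fractional occupancy per labelled conformational state.

    With as many components as labels, components map to labels strictly by
    ascending mean.  With fewer components (BIC selected k < 3), each
    component is assigned to the label whose canonical reference mean lies
    closest, and absent states are reported as 0 rather than forced into
    the fit.
    """
    labels = list(state_labels)
    fractions = {lab: 0.0 for lab in labels}
    if fit.k == len(labels):
        for lab, w in zip(labels, fit.weights):
            fractions[lab] += float(w)
        return fractions
    refs = reference_means or REFERENCE_MEANS
    ref_vals = np.asarray([refs[lab] for lab in labels])
    for m, w in zip(fit.means, fit.weights):
        lab = labels[int(np.argmin(np.abs(ref_vals - m)))]
        fractions[lab] += float(w)
    return fractions


def assign_states(
    trajectory: FretTrajectory,
    fit: GaussianMixtureFit,
    min_dwell_frames: int = 3,
    smooth_frames: int = 5,
) -> np.ndarray:
    """Per-frame state labels with hysteresis and a minimum-dwell rule.

    The efficiency series is median-filtered over ``smooth_frames`` frames
    (single-frame noise spikes cannot cross a state boundary), frames are
    provisionally labelled by the nearest component (boundaries at midpoints
    between adjacent means), and a label change is accepted only when the
    new label persists for at least ``min_dwell_frames`` consecutive frames
    *and* the mean efficiency over that run lies on the new state's side of
    the midpoint (the hysteresis check, evaluated on the unfiltered series).
    Invalid frames are labelled -1.
    """
    if fit.k < 1:
        raise ValueError("mixture fit must have at least one component")
    e = trajectory.efficiency
    n = len(e)
    if n == 0:
        raise ValueError("empty trajectory")
    labels = np.full(n, -1, dtype=int)
    valid_idx = np.flatnonzero(trajectory.valid)
    if valid_idx.size == 0:
        return labels
    e_v = e[valid_idx]
    if smooth_frames > 1 and e_v.size >= smooth_frames:
        from scipy.signal import medfilt

        win = smooth_frames if smooth_frames % 2 == 1 else smooth_frames + 1
        e_s = medfilt(e_v, kernel_size=win)
        # medfilt zero-pads the ends; keep the raw values there
        half = win // 2
        e_s[:half] = e_v[:half]
        e_s[-half:] = e_v[-half:]
    else:
        e_s = e_v
    boundaries = 0.5 * (fit.means[:-1] + fit.means[1:])
    raw_v = np.searchsorted(boundaries, e_s)
    # run-length encode the provisional labels over valid frames
    change = np.flatnonzero(np.diff(raw_v)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(raw_v)]))
    accepted = np.empty(len(raw_v), dtype=int)
    lengths = ends - starts
    # the starting state is the first sustained run (longest run as fallback),
    # so a noisy opening frame cannot masquerade as an initial state
    sustained = np.flatnonzero(lengths >= min_dwell_frames)
    first = sustained[0] if sustained.size else int(np.argmax(lengths))
    current = int(raw_v[starts[first]])
    accepted[: ends[first]] = current
    for s, t in zip(starts[first + 1:], ends[first + 1:]):
        run_label = int(raw_v[s])
        if run_label != current and (t - s) >= min_dwell_frames:
            run_mean = float(np.mean(e_v[s:t]))
            if int(np.searchsorted(boundaries, run_mean)) == run_label:
                current = run_label
        accepted[s:t] = current
    labels[valid_idx] = accepted
    return labels
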