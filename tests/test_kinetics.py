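"""Cross-correlation, event classification and dwell-time kinetics."""

from dataclasses import replace

import numpy as np
import pytest

import smfretkit as sk
from smfretkit.kinetics import (
    classify_event,
    classify_events,
    cross_correlation,
    cumulative_intensity,
    detect_interconversion,
    dwell_histogram_fit,
    per_state_reaction_rates,
    reacted_fractions,
)


def _trace(donor, acceptor, dt=1.0, **kw):
    donor = np.asarray(donor, dtype=float)
    return sk.Trace(
        molecule_id=kw.pop("molecule_id", 0),
        time=np.arange(len(donor)) * dt,
        donor=donor,
        acceptor=np.asarray(acceptor, dtype=float),
        **kw,
    )


def brute_force_xcorr(d, a, max_lag, denominator="mean_of_products"):
    """Literal double-loop evaluation of the cross-correlation definition."""
    d = np.asarray(d, float)
    a = np.asarray(a, float)
    n = len(d)
    md, ma = d.mean(), a.mean()
    norm = np.mean(d * a) if denominator == "mean_of_products" else md * ma
    g = np.zeros(max_lag + 1)
    for tau in range(max_lag + 1):
        s = 0.0
        for t in range(n - tau):
            s += (d[t] - md) * (a[t + tau] - ma)
        g[tau] = s / (n * norm)
    return g


# --------------------------------------------------------------------------- #
# Cross-correlation
# --------------------------------------------------------------------------- #
def test_constant_channels_give_zero():
    tr = _trace(np.full(50, 10.0), np.full(50, 5.0))
    assert np.allclose(cross_correlation(tr, 10).g, 0.0, atol=1e-12)


def test_four_point_hand_case():
    tr = _trace([1, 2, 1, 2], [2, 1, 2, 1])
    g = cross_correlation(tr, 0).g
    # deviations (-.5,.5,-.5,.5) x (.5,-.5,.5,-.5): sum = -1; N*mean(dd*aa) = 4*2
    assert g[0] == pytest.approx(-0.125, abs=1e-12)
    assert g[0] == pytest.approx(brute_force_xcorr([1, 2, 1, 2], [2, 1, 2, 1], 0)[0])


def test_matches_brute_force_on_random_traces():
    rng = np.random.default_rng(8)
    for _ in range(5):
        d = rng.normal(100, 10, 120)
        a = rng.normal(80, 10, 120)
        tr = _trace(d, a)
        for denom in ("mean_of_products", "product_of_means"):
            g = cross_correlation(tr, 15, denominator=denom).g
            assert np.allclose(g, brute_force_xcorr(d, a, 15, denom), atol=1e-9)


def test_anticorrelated_switching_negative_g0():
    """Two-state anticorrelated switching gives G(0) < 0 decaying with lag."""
    rng = np.random.default_rng(4)
    state = np.cumsum(rng.random(2000) < 0.05) % 2  # switch every ~20 frames
    d = np.where(state == 0, 800.0, 300.0) + rng.normal(0, 20, 2000)
    a = np.where(state == 0, 200.0, 700.0) + rng.normal(0, 20, 2000)
    tr = _trace(d, a, dt=0.1)
    xc = cross_correlation(tr, 100)
    assert xc.g[0] < 0
    assert abs(xc.g[100]) < 0.5 * abs(xc.g[0])
    assert np.allclose(xc.g, brute_force_xcorr(d, a, 100), atol=1e-9)


def test_zero_denominator_rejected():
    tr = _trace(np.zeros(10), np.zeros(10))
    with pytest.raises(ZeroDivisionError):
        cross_correlation(tr, 2)


def test_max_lag_bounds_checked():
    tr = _trace(np.ones(10), np.ones(10))
    with pytest.raises(ValueError):
        cross_correlation(tr, 10)


# --------------------------------------------------------------------------- #
# Event classification
# --------------------------------------------------------------------------- #
def _reaction_like_trace(event_frame=None, kind="transfer", n=100, noise=20.0, seed=0):
    """Hand-built 1 s/frame real-time trace with a known event signature."""
    rng = np.random.default_rng(seed)
    i_d, i_a = sk.invert_efficiency(0.71, 1000.0)
    d = np.full(n, i_d)
    a = np.full(n, i_a)
    if event_frame is not None:
        if kind == "transfer":
            d[event_frame:] = 0.0
            a[event_frame:] = 0.0
        elif kind == "acceptor_bleach":
            a[event_frame:] = 0.0
            d[event_frame:] = 1000.0
    d += rng.normal(0, noise, n)
    a += rng.normal(0, noise, n)
    return _trace(d, a, injection_frame=10)


def test_transfer_event_classified_with_dwell():
    tr = _reaction_like_trace(event_frame=40)
    ev = classify_event(tr)
    assert ev.kind == "transfer_FRET"
    assert abs(ev.event_frame - 40) <= 1
    assert ev.dwell_s == pytest.approx((ev.event_frame - 10) * 1.0)
    assert ev.initial_state == "high"


def test_acceptor_bleach_with_donor_recovery():
    tr = _reaction_like_trace(event_frame=50, kind="acceptor_bleach")
    ev = classify_event(tr)
    assert ev.kind == "acceptor_photobleach"
    assert abs(ev.event_frame - 50) <= 1


def test_flat_trace_unreacted():
    tr = _reaction_like_trace(event_frame=None)
    ev = classify_event(tr)
    assert ev.kind == "unreacted"
    assert ev.event_frame is None and ev.dwell_s is None


def test_donor_only_transfer():
    rng = np.random.default_rng(2)
    d = np.full(80, 1000.0)
    d[30:] = 0.0
    tr = _trace(d + rng.normal(0, 20, 80), rng.normal(0, 20, 80), injection_frame=5)
    ev = classify_event(tr)
    assert ev.kind == "transfer_donor_only"
    assert ev.donor_only


def test_event_during_injection_excluded():
    tr = _reaction_like_trace(event_frame=8)
    ev = classify_event(tr)
    assert ev.excluded
    assert ev.dwell_s is None


def test_classifier_recovers_generator_events(reaction_dataset):
    """Classification against generator truth: accuracy >= 95%, ambiguous < 2%."""
    events = classify_events(reaction_dataset)
    mapping = {
        "transfer": ("transfer_FRET", "transfer_donor_only"),
        "acceptor_bleach": ("acceptor_photobleach",),
        "donor_bleach": ("donor_photobleach",),
        "none": ("unreacted",),
    }
    correct = [
        e.kind in mapping[g.event_kind]
        for e, g in zip(events, reaction_dataset.ground_truth)
    ]
    assert np.mean(correct) >= 0.95
    assert np.mean([e.kind == "ambiguous" for e in events]) < 0.02


def test_no_fret_recovery_after_called_transfers(reaction_dataset):
    """Transfer calls never show the FRET pair coming back."""
    events = classify_events(reaction_dataset)
    for tr, ev in zip(reaction_dataset, events):
        if ev.kind != "transfer_FRET":
            continue
        post = tr.acceptor[ev.event_frame:]
        sigma = np.std(tr.acceptor[: ev.event_frame]) or 1.0
        # no sustained return of acceptor signal above noise
        above = post > 5 * sigma
        assert not np.any(above[:-2] & above[1:-1] & above[2:])


def test_transfer_dwells_match_truth(reaction_dataset):
    events = classify_events(reaction_dataset)
    diffs = [
        abs(e.event_frame - g.event_frame)
        for e, g in zip(events, reaction_dataset.ground_truth)
        if e.kind == "transfer_FRET" and g.event_kind == "transfer"
    ]
    assert np.mean(np.asarray(diffs) <= 1) > 0.98


# --------------------------------------------------------------------------- #
# Reacted fractions
# --------------------------------------------------------------------------- #
def _call(kind, dwell=None, state=None, donor_only=False):
    from smfretkit.kinetics import EventCall

    return EventCall(0, kind, 10 if dwell else None, dwell, state, donor_only)


def test_all_unreacted_fraction():
    fr = reacted_fractions([_call("unreacted")] * 5)
    assert fr["unreacted"] == 100.0
    assert fr["transfer_combined"] == 0.0


def test_fraction_identity():
    events = [_call("transfer_FRET", dwell=5.0)] * 60 + [_call("unreacted")] * 40
    fr = reacted_fractions(events)
    assert fr["transfer_combined"] == pytest.approx(60.0)


def test_reaction_preset_transfer_fraction(reaction_dataset):
    events = classify_events(reaction_dataset)
    fr = reacted_fractions(events)
    assert abs(fr["transfer_combined"] - 60.0) < 6.0


def test_empty_events_rejected():
    with pytest.raises(ValueError):
        reacted_fractions([])


# --------------------------------------------------------------------------- #
# Dwell-time fits
# --------------------------------------------------------------------------- #
def test_mono_rate_recovered_within_two_se():
    rng = np.random.default_rng(15)
    dwells = rng.exponential(1 / 0.05, 1000)
    fit = dwell_histogram_fit(dwells, model="mono", frame_interval=1.0)
    assert fit.model == "mono"
    assert abs(fit.rates[0] - 0.05) < 2 * fit.rate_se[0]
    # unbinned MLE cross-check: 1/mean
    assert fit.mle_rates[0] == pytest.approx(1 / dwells.mean(), rel=1e-9)


def test_auto_selects_biexponential_on_mixture():
    rng = np.random.default_rng(16)
    dwells = np.concatenate(
        [rng.exponential(1 / 0.2, 1000), rng.exponential(1 / 0.01, 1000)]
    )
    fit = dwell_histogram_fit(dwells, model="auto", frame_interval=1.0)
    assert fit.model == "bi"
    assert fit.aic_bi < fit.aic_mono
    k_fast, k_slow = fit.mle_rates
    assert 0.1 < k_fast < 0.4
    assert 0.005 < k_slow < 0.02


def test_auto_selects_mono_on_single_exponential():
    rng = np.random.default_rng(17)
    dwells = rng.exponential(20.0, 1000)
    fit = dwell_histogram_fit(dwells, model="auto", frame_interval=1.0)
    assert fit.model == "mono"


def test_degenerate_identical_dwells():
    with pytest.warns(RuntimeWarning, match="identical"):
        fit = dwell_histogram_fit(np.full(20, 10.0), model="auto")
    assert fit.model == "mono"
    assert fit.rates[0] == pytest.approx(0.1)


def test_too_few_dwells_rejected():
    with pytest.raises(ValueError, match="10 dwell"):
        dwell_histogram_fit([1.0, 2.0])


def test_rate_recovery_unbiased_across_seeds():
    """Mean fitted rate over replicates stays within 5% of truth."""
    ks = []
    for seed in range(20):
        rng = np.random.default_rng(300 + seed)
        fit = dwell_histogram_fit(
            rng.exponential(1 / 0.05, 500), model="mono", frame_interval=1.0
        )
        ks.append(fit.rates[0])
    assert abs(np.mean(ks) - 0.05) < 0.0025


# --------------------------------------------------------------------------- #
# Per-state rates, interconversion, cumulative intensity
# --------------------------------------------------------------------------- #
def test_per_state_rates_ordered_high_over_low():
    rng = np.random.default_rng(21)
    events = [
        _call("transfer_FRET", dwell=float(d), state="high")
        for d in rng.exponential(10.0, 200)  # k = 0.1
    ] + [
        _call("transfer_FRET", dwell=float(d), state="low")
        for d in rng.exponential(100.0, 200)  # k = 0.01
    ]
    rates = per_state_reaction_rates(events)
    ratio = rates["high"]["median_rate_per_s"] / rates["low"]["median_rate_per_s"]
    assert rates["high"]["median_rate_per_s"] > rates["low"]["median_rate_per_s"]
    assert 5 < ratio < 20
    assert rates["intermediate"] == {"n": 0}


def test_per_state_single_event_degenerate_quartiles():
    rates = per_state_reaction_rates([_call("transfer_FRET", dwell=10.0, state="high")])
    assert rates["high"]["n"] == 1
    assert rates["high"]["median_rate_per_s"] == pytest.approx(0.1)
    assert rates["high"]["q1_rate_per_s"] == rates["high"]["q3_rate_per_s"]


def test_interconversion_flags_match_truth(default_dataset):
    from smfretkit.reporting import masked_trajectories
    from smfretkit.populations import fit_gaussian_mixture

    trajs, events = masked_trajectories(default_dataset, sk.FretParams())
    samples = sk.molecule_mean_efficiencies(trajs)
    fit = fit_gaussian_mixture(samples, k=3)
    flagged = sum(detect_interconversion(t, fit)[0] for t in trajs)
    truth = sum(g.dynamic for g in default_dataset.ground_truth)
    n = len(default_dataset)
    assert abs(100 * flagged / n - 1.0) <= 1.0  # ~1% of one-minute traces
    assert abs(flagged - truth) <= 0.01 * n


def test_generator_marked_dynamic_trace_detected():
    from smfretkit.populations import fit_gaussian_mixture

    cfg = sk.SimulationConfig(dynamic_fraction=1.0, interconversion_rate=0.05, seed=23)
    ds = sk.simulate_dataset(cfg, 60)
    trajs = [sk.compute_fret_trajectory(tr) for tr in ds]
    fit = fit_gaussian_mixture(
        np.concatenate([t.efficiency[t.valid] for t in trajs]), k=3
    )
    hits = total = 0
    for traj, g in zip(trajs, ds.ground_truth):
        switches = np.flatnonzero(np.diff(g.state_path[: g.event_frame or len(g.state_path)]))
        if len(switches) != 1 or g.event_kind != "none":
            continue
        # only count switches with enough frames on either side to detect
        if not (10 < switches[0] < len(g.state_path) - 10):
            continue
        total += 1
        dynamic, transitions = detect_interconversion(traj, fit)
        hits += dynamic and len(transitions) == 1
    assert total >= 5
    assert hits / total >= 0.8


def test_cumulative_intensity_flat_and_decaying():
    cfg = replace(sk.preset("thioester_UEV_only"), seed=31, bleach_rate_acceptor=0.0005)
    flat = sk.simulate_dataset(cfg, 150)
    cum_flat = cumulative_intensity(flat)
    early = cum_flat["total"][:20].mean()
    late = cum_flat["total"][-20:].mean()
    assert late > 0.65 * early

    rx = sk.simulate_dataset(replace(sk.preset("thioester_reaction"), seed=31), 150)
    cum_rx = cumulative_intensity(rx)
    assert cum_rx["total"][-20:].mean() < 0.6 * cum_rx["total"][:10].mean()
    # decay is monotone apart from noise: compare window means
    w = cum_rx["total"].reshape(-1, 30).mean(axis=1)
    assert np.all(np.diff(w[:5]) < 0)


def test_cumulative_intensity_single_molecule(make_constant_trace):
    tr = make_constant_trace(e=0.5, n=50)
    cum = cumulative_intensity(sk.TraceSet([tr]))
    assert np.allclose(cum["donor"], tr.donor)
    assert np.allclose(cum["acceptor"], tr.acceptor)
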