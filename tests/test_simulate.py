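"""Synthetic trajectory generator: ground-truth consistency and statistics."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import smfretkit as sk
from smfretkit.simulate import PRESETS, SimulationConfig, preset


# --------------------------------------------------------------------------- #
# Configuration validation
# --------------------------------------------------------------------------- #
@pytest.mark.parametrize(
    "kwargs",
    [
        dict(state_occupancies=(0.5, 0.5, 0.5)),  # does not sum to 1
        dict(state_means=(0.7, 0.5, 0.3), state_occupancies=(0.3, 0.3, 0.4)),
        dict(bleach_rate_donor=-0.1),
        dict(dynamic_fraction=1.5),
        dict(n_frames=0),
        dict(injection_frame=1000),
        dict(alpha=0.0),
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)


def test_unknown_preset_rejected():
    with pytest.raises(KeyError, match="unknown preset"):
        preset("no_such_condition")


def test_presets_cover_all_conditions():
    expected = {
        "default",
        "isopeptide_alone_12C",
        "isopeptide_alone_22C",
        "plus_UEV",
        "plus_UEV_RNF4",
        "thioester_reaction",
        "thioester_UEV_only",
    }
    assert expected == set(PRESETS)


def test_config_yaml_roundtrip(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("preset: thioester_reaction\nseed: 5\nn_frames: 100\n")
    cfg = sk.load_config(p)
    assert cfg.condition == "thioester_reaction"
    assert cfg.seed == 5 and cfg.n_frames == 100


# --------------------------------------------------------------------------- #
# Equilibrium traces
# --------------------------------------------------------------------------- #
def test_noise_free_roundtrip_is_exact(noise_free_config):
    """Analysis of a noise-free trace reproduces the state mean exactly."""
    cfg = replace(
        noise_free_config,
        state_means=(0.71,),
        state_occupancies=(1.0,),
    )
    tr, gt = sk.simulate_equilibrium_trace(cfg, molecule_seed=1)
    traj = sk.compute_fret_trajectory(tr)
    assert np.allclose(traj.efficiency, 0.71, atol=1e-12)
    assert gt.event_kind == "none"


def test_static_fraction_never_switches():
    cfg = SimulationConfig(dynamic_fraction=0.0, n_frames=200, seed=3)
    ds = sk.simulate_dataset(cfg, 200)
    assert not any(g.dynamic for g in ds.ground_truth)


def test_acceptor_bleach_dwell_matches_exponential_mean():
    """Drawn acceptor-bleach times follow the configured exponential."""
    cfg = SimulationConfig(
        bleach_rate_donor=0.0,
        bleach_rate_acceptor=0.02,
        frame_interval=1.0,
        n_frames=2000,
        dynamic_fraction=0.0,
        noise_sigma=0.0,
        seed=9,
    )
    ds = sk.simulate_dataset(cfg, 2000)
    dwells = np.array(
        [
            g.event_frame * cfg.frame_interval
            for g in ds.ground_truth
            if g.event_kind == "acceptor_bleach"
        ]
    )
    assert dwells.size > 1900  # observation window is 40 mean lifetimes
    se = 50.0 / np.sqrt(dwells.size)
    assert abs(dwells.mean() - 50.0) < 2 * se + 1.0  # +1 frame discretisation


def test_event_times_match_configured_exponential_ks():
    cfg = SimulationConfig(
        bleach_rate_donor=0.0,
        bleach_rate_acceptor=0.05,
        frame_interval=0.1,
        n_frames=2000,
        dynamic_fraction=0.0,
        noise_sigma=0.0,
        seed=5,
    )
    ds = sk.simulate_dataset(cfg, 2000)
    dwells = np.array(
        [
            g.event_frame * cfg.frame_interval
            for g in ds.ground_truth
            if g.event_kind == "acceptor_bleach"
        ]
    )
    # subtract half a frame: event frames are the ceiling of the event time
    res = stats.kstest(dwells - 0.05, stats.expon(scale=20.0).cdf)
    assert res.pvalue > 0.01


def test_acceptor_bleach_gives_donor_recovery(noise_free_config):
    cfg = replace(noise_free_config, bleach_rate_acceptor=0.5, n_frames=100, seed=2)
    ds = sk.simulate_dataset(cfg, 50)
    hits = 0
    for tr, g in zip(ds, ds.ground_truth):
        if g.event_kind != "acceptor_bleach":
            continue
        hits += 1
        f = g.event_frame
        assert tr.acceptor[f] == 0.0
        assert tr.donor[f] == cfg.total_intensity
        assert tr.donor[f] > tr.donor[f - 1]
    assert hits > 10


# --------------------------------------------------------------------------- #
# Reaction traces
# --------------------------------------------------------------------------- #
def test_zero_rates_give_no_transfer():
    cfg = replace(
        preset("thioester_reaction"),
        reaction_rate_high=0.0,
        reaction_rate_low=0.0,
        seed=4,
    )
    ds = sk.simulate_dataset(cfg, 200)
    assert not any(g.event_kind == "transfer" for g in ds.ground_truth)


def test_no_transfer_before_injection():
    cfg = replace(preset("thioester_reaction"), seed=8)
    ds = sk.simulate_dataset(cfg, 400)
    for g in ds.ground_truth:
        if g.event_kind == "transfer":
            assert g.event_frame > cfg.injection_frame


def test_transfer_dominates_when_rate_overwhelms_bleaching():
    """With k_transfer >> k_bleach the competing-exponentials win probability
    k_r / (k_r + k_bleach) exceeds 0.95."""
    cfg = SimulationConfig(
        state_means=(0.71,),
        state_occupancies=(1.0,),
        frame_interval=1.0,
        n_frames=300,
        injection_frame=5,
        reaction_rate_high=1.0,
        bleach_rate_donor=0.001,
        bleach_rate_acceptor=0.004,
        dynamic_fraction=0.0,
        seed=6,
    )
    ds = sk.simulate_dataset(cfg, 500)
    frac = np.mean([g.event_kind == "transfer" for g in ds.ground_truth])
    assert frac >= 0.95


def test_transfer_removes_both_channels_without_recovery():
    cfg = replace(preset("thioester_reaction"), noise_sigma=0.0, seed=12)
    ds = sk.simulate_dataset(cfg, 100)
    seen = 0
    for tr, g in zip(ds, ds.ground_truth):
        if g.event_kind != "transfer":
            continue
        seen += 1
        assert np.all(tr.donor[g.event_frame:] == 0.0)
        assert np.all(tr.acceptor[g.event_frame:] == 0.0)
    assert seen > 20


def test_donor_only_fraction_recovered():
    cfg = replace(preset("thioester_reaction"), donor_only_fraction=0.2, seed=10)
    ds = sk.simulate_dataset(cfg, 1000)
    frac = np.mean([g.donor_only for g in ds.ground_truth])
    assert abs(frac - 0.2) < 0.03  # ~2.4 binomial s.d.


def test_injection_frame_required_for_reaction():
    cfg = SimulationConfig()
    with pytest.raises(ValueError, match="injection_frame"):
        sk.simulate_reaction_trace(cfg, molecule_seed=0)


def test_reaction_rates_forbidden_in_equilibrium():
    cfg = preset("thioester_reaction")
    with pytest.raises(ValueError):
        sk.simulate_equilibrium_trace(cfg, molecule_seed=0)


# --------------------------------------------------------------------------- #
# Dataset-level behaviour
# --------------------------------------------------------------------------- #
def test_dataset_deterministic_for_fixed_seed():
    cfg = replace(preset("default"), n_frames=100, seed=77)
    a = sk.simulate_dataset(cfg, 20)
    b = sk.simulate_dataset(cfg, 20)
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.donor, tb.donor)
        assert np.array_equal(ta.acceptor, tb.acceptor)


def test_different_seeds_differ():
    cfg = replace(preset("default"), n_frames=50)
    a = sk.simulate_dataset(replace(cfg, seed=1), 5)
    b = sk.simulate_dataset(replace(cfg, seed=2), 5)
    assert not np.array_equal(a[0].donor, b[0].donor)


def test_initial_state_counts_multinomial():
    cfg = SimulationConfig(
        state_occupancies=(0.3, 0.3, 0.4), n_frames=20, seed=13, dynamic_fraction=0.0
    )
    ds = sk.simulate_dataset(cfg, 3000)
    counts = np.bincount([g.initial_state for g in ds.ground_truth], minlength=3)
    for c, p in zip(counts, (0.3, 0.3, 0.4)):
        sd = np.sqrt(3000 * p * (1 - p))
        assert abs(c - 3000 * p) < 3 * sd


def test_single_molecule_dataset():
    cfg = replace(preset("default"), n_frames=30)
    ds = sk.simulate_dataset(cfg, 1)
    assert len(ds) == 1
    with pytest.raises(ValueError):
        sk.simulate_dataset(cfg, 0)
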