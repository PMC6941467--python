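"""Extreme-amplitude screening, super-channel, noise bands, thresholds, blocks."""

import numpy as np
import pytest

from fasciq.config import PipelineConfig
from fasciq.detect import (
    NoiseBlock,
    Potential,
    apply_inclusion_threshold,
    build_superchannel,
    compute_noise_band,
    exclude_noisy_blocks,
    median_noise,
    screen_channel,
    screen_potentials,
)
from fasciq.recording import GridRecording, default_grid_positions
from fasciq.synth import SynthParams, generate_recording, spike_template
from fasciq.pipeline import run_pipeline

FS = 2048.0


def _mono_recording(x):
    return GridRecording(
        signal=np.asarray(x, dtype=float).reshape(-1, 1), sampling_rate=FS,
        grid_rows=1, grid_cols=1, channel_positions={0: (0, 0)},
    )


def _potential(span, channel=0, p2t=0.0, peak_time=None, noise_band=None):
    return Potential(
        peak_time_s=peak_time if peak_time is not None else span[0] / FS,
        span=span, channel=channel, peak_uv=p2t, trough_uv=0.0, p2t_uv=p2t,
        noise_band_uv=noise_band,
    )


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def test_zero_channel_yields_no_events(cfg):
    assert screen_channel(np.zeros(4096), FS, cfg) == []


def test_single_biphasic_spike_in_noise_is_one_event(cfg):
    """White noise rarely pairs opposite-polarity extremes within 10 ms,
    so an inserted 300 μV biphasic spike is the only event found."""
    rng = np.random.default_rng(0)
    x = rng.normal(0, 5.0, size=int(60 * FS))
    tpl = spike_template(FS) * 300.0
    i0 = int(30.0 * FS)
    x[i0: i0 + len(tpl)] += tpl
    events = screen_channel(x, FS, cfg)
    assert len(events) == 1
    s, e = events[0]
    assert s <= i0 + np.argmax(np.abs(tpl)) < e


def test_suprathreshold_occupancy_within_budget(cfg):
    rng = np.random.default_rng(1)
    x = rng.normal(0, 5.0, size=int(30 * FS))
    f = cfg.extreme_occupancy_fraction
    # outward-rounded quantiles, as the screen uses them
    hi = np.quantile(x, 1 - f / 2, method="higher")
    lo = np.quantile(x, f / 2, method="lower")
    occupancy = np.mean((x > hi) | (x < lo))
    assert occupancy <= f + 1e-9


# ---------------------------------------------------------------------------
# super-channel
# ---------------------------------------------------------------------------

def _spike_grid(amplitudes, at_s=1.0, duration_s=3.0, second_at_s=None):
    """Recording with one spike over many channels at given peak amplitudes."""
    n_ch = len(amplitudes)
    sig = np.zeros((int(duration_s * FS), n_ch))
    tpl = spike_template(FS)
    i0 = int(at_s * FS)
    for ch, a in enumerate(amplitudes):
        sig[i0: i0 + len(tpl), ch] += a * tpl
    if second_at_s is not None:
        i1 = int(second_at_s * FS)
        sig[i1: i1 + len(tpl), -1] += 100.0 * tpl
    rng = np.random.default_rng(9)
    sig += rng.normal(0, 0.5, size=sig.shape)
    return GridRecording(
        signal=sig, sampling_rate=FS, grid_rows=1, grid_cols=n_ch,
        channel_positions=default_grid_positions(1, n_ch),
    )


def test_merge_takes_greatest_peak_trough_channel(cfg):
    amps = np.linspace(50, 200, 12)
    rec = _spike_grid(amps)
    sc = build_superchannel(rec, screen_potentials(rec, cfg), cfg)
    assert len(sc.potentials) == 1
    assert sc.potentials[0].channel == 11  # the 200 μV channel
    assert sc.potentials[0].p2t_uv == pytest.approx(200 * np.ptp(spike_template(FS)), rel=0.05)


def test_distant_spikes_stay_separate_and_ordered(cfg):
    rec = _spike_grid([200.0, 0.0, 0.0], at_s=1.0, second_at_s=1.5)
    sc = build_superchannel(rec, screen_potentials(rec, cfg), cfg)
    assert len(sc.potentials) == 2
    t = [p.peak_time_s for p in sc.potentials]
    assert t == sorted(t)
    assert t[0] == pytest.approx(1.0, abs=0.02) and t[1] == pytest.approx(1.5, abs=0.02)
    spans = [p.span for p in sc.potentials]
    assert spans[0][1] <= spans[1][0]


def test_merge_is_independent_of_channel_order(cfg):
    amps = np.linspace(50, 200, 12)
    rec = _spike_grid(amps)
    events = screen_potentials(rec, cfg)
    sc1 = build_superchannel(rec, events, cfg)
    shuffled = {cid: events[cid] for cid in reversed(list(events))}
    sc2 = build_superchannel(rec, shuffled, cfg)
    assert [(p.span, p.channel, p.p2t_uv) for p in sc1.potentials] == [
        (p.span, p.channel, p.p2t_uv) for p in sc2.potentials
    ]


# ---------------------------------------------------------------------------
# noise bands
# ---------------------------------------------------------------------------

def test_noise_band_constant_positive_signal(cfg):
    rec = _mono_recording(np.full(int(3 * FS), 3.0))
    p = _potential((int(1.4 * FS), int(1.5 * FS)))
    assert compute_noise_band(rec, p, [p], cfg) == pytest.approx(3.0)


def test_noise_band_alternating_signal(cfg):
    x = np.tile([2.0, -2.0], int(1.5 * FS))
    p = _potential((int(1.4 * FS), int(1.5 * FS)))
    assert compute_noise_band(_mono_recording(x), p, [p], cfg) == pytest.approx(4.0)


def test_noise_band_matches_half_normal_closed_form(cfg):
    """Monte-Carlo mean of the Gaussian noise band is 2·σ·sqrt(2/π)."""
    rng = np.random.default_rng(3)
    sigma = 5.0
    vals = []
    for _ in range(50):
        rec = _mono_recording(rng.normal(0, sigma, size=int(3 * FS)))
        p = _potential((int(1.5 * FS), int(1.5 * FS) + 30))
        vals.append(compute_noise_band(rec, p, [p], cfg))
    expected = 2 * sigma * np.sqrt(2 / np.pi)
    assert np.mean(vals) == pytest.approx(expected, rel=0.02)


def test_noise_band_excludes_other_potentials(cfg):
    """A large neighbouring potential must not inflate the noise band."""
    x = np.full(int(3 * FS), 1.0)
    s = int(1.5 * FS)
    x[s - 200: s - 100] = 500.0  # inside the flanking window
    rec = _mono_recording(x)
    p = _potential((s, s + 30))
    other = _potential((s - 200, s - 100))
    assert compute_noise_band(rec, p, [p, other], cfg) == pytest.approx(1.0)


def test_median_noise_conventions():
    mk = lambda nb: _potential((0, 10), noise_band=nb)
    assert median_noise([mk(2.0), mk(3.0), mk(100.0)]) == pytest.approx(3.0)
    assert median_noise([mk(7.0)]) == pytest.approx(7.0)
    assert median_noise([mk(2.0), mk(4.0)]) == pytest.approx(3.0)
    assert median_noise([_potential((0, 10))]) is None


# ---------------------------------------------------------------------------
# inclusion threshold and noisy blocks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "noise_band,p2t,expected_at_inc,included",
    [
        (1.0, 100.0, 8.0, True),
        (0.0, 0.5, 0.0, True),        # zero noise: everything passes
        (12.5, 99.0, 100.0, False),   # threshold forced to 8 x 12.5
    ],
)
def test_inclusion_threshold_is_eight_times_noise(cfg, noise_band, p2t, expected_at_inc, included):
    p = _potential((0, 10), p2t=p2t, noise_band=noise_band)
    apply_inclusion_threshold(p, cfg)
    assert p.at_inc_uv == pytest.approx(expected_at_inc)
    assert p.included is included


def test_undefined_noise_band_excludes_potential(cfg):
    p = _potential((0, 10), p2t=500.0, noise_band=None)
    assert not apply_inclusion_threshold(p, cfg)
    assert p.exclusion_reason == "noisy_block"


@pytest.mark.parametrize(
    "at_incs,excluded,rule",
    [
        ([120.0, 130.0, 50.0], True, "half_above_atexc"),
        ([50.0, 60.0, 210.0], True, "any_above_double"),
        ([50.0, 60.0, 110.0], False, None),
    ],
)
def test_noisy_block_rules(cfg, at_incs, excluded, rule):
    pots = []
    for i, ai in enumerate(at_incs):
        p = _potential((i * 100, i * 100 + 10), p2t=1000.0, peak_time=0.5 + i)
        p.noise_band_uv = ai / cfg.at_inc_noise_factor
        apply_inclusion_threshold(p, cfg)
        pots.append(p)
    blocks = exclude_noisy_blocks(pots, 5.0, cfg)
    assert len(blocks) == 1
    assert blocks[0].excluded is excluded
    assert blocks[0].rule_fired == rule
    if excluded:
        assert all(not p.included for p in pots)
        assert all(p.exclusion_reason == "noisy_block" for p in pots)


def test_empty_block_never_excluded(cfg):
    blocks = exclude_noisy_blocks([], 12.5, cfg)
    assert len(blocks) == 3
    assert not any(b.excluded for b in blocks)
    assert blocks[-1].duration_s == pytest.approx(2.5)  # final partial block


def test_at_inc_monotone_in_noise_band(cfg):
    bands = np.linspace(0.1, 50, 20)
    at = []
    for nb in bands:
        p = _potential((0, 10), p2t=1e9, noise_band=float(nb))
        apply_inclusion_threshold(p, cfg)
        at.append(p.at_inc_uv)
    slopes = np.diff(at) / np.diff(bands)
    np.testing.assert_allclose(slopes, cfg.at_inc_noise_factor)


# ---------------------------------------------------------------------------
# end-to-end detection behaviour
# ---------------------------------------------------------------------------

def test_clean_recordings_recall_and_no_noisy_blocks(clean_runs):
    """Low-noise recordings: every truth spike recovered within 10 ms,
    no spurious inclusions, and zero excluded 5 s blocks."""
    for truth, result in clean_runs:
        inc = np.array([p.peak_time_s for p in result.superchannel.potentials if p.included])
        tt = truth.spike_times()
        hits = sum(np.min(np.abs(inc - t)) <= 0.010 for t in tt)
        assert hits / len(tt) >= 0.95
        assert not any(b.excluded for b in result.noise_blocks)
        spurious = sum(np.min(np.abs(tt - t)) > 0.010 for t in inc)
        assert spurious == 0


def test_excluded_blocks_increase_with_noise():
    """More injected noise can only push more 5 s blocks over threshold."""
    counts = []
    for sd in (2.0, 8.0, 40.0):
        per_seed = []
        for seed in (21, 22):
            rec, _ = generate_recording(
                SynthParams(duration_s=30.0, fasciculation_rate_per_min=40.0,
                            noise_sd_uv=sd, seed=seed)
            )
            res = run_pipeline(rec, PipelineConfig(strategy="0"))
            per_seed.append(sum(b.excluded for b in res.noise_blocks))
        counts.append(np.mean(per_seed))
    assert counts[0] <= counts[1] <= counts[2]
    assert counts[2] > counts[0]
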