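"""Synthetic grid surface-EMG generator with ground truth.

Emulates the signal content the pipeline must handle, with every spike
time and label known:

* **Fasciculations** — random, independent discharges of single motor
  units, modelled as a homogeneous Poisson process (exponential
  inter-spike intervals) thinned by an absolute refractory period.
* **Voluntary motor units** — regular firing at 4–12 Hz inside declared
  epochs, with multiplicative Gaussian ISI jitter (CV 0.12 by default) so
  that interval histograms develop the narrow 100–200 ms peak typical of
  low-force recruitment.  Generated ISIs are capped just below the 250 ms
  train cutoff so every generated train satisfies the detector's own
  definition of voluntary activity.
* **Multiplets** — paired discharges: a partner spike with identical
  morphology follows the parent at a short (< 50 ms) gap.
* **Waveforms** — each spike is a triphasic Hanning-windowed template
  (~15 ms) placed at a random grid epicentre and scaled across channels
  by exponential spatial decay, reaching at least 10 channels above a
  quarter of the peak amplitude (the premise of multi-channel motor-unit
  identification).  Per-spike amplitudes scatter log-normally.
* **Noise** — additive Gaussian noise, 50 Hz sinusoidal line
  interference, slow sinusoidal baseline drift, and optional dead (flat)
  channels.

Everything is driven by one seed; identical parameters and seed give a
bit-identical recording and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .recording import GridRecording, default_grid_positions

SPIKE_TEMPLATE_MS = 15.0
SPATIAL_DECAY_CHANNELS = 1.7     # e-folding distance of spike amplitude, in electrode pitches
AMP_LOGNORMAL_SIGMA = 0.3
DRIFT_HZ = 0.2


@dataclass
class SynthParams:
    """Generator settings; defaults emulate a relaxed biceps recording."""

    duration_s: float = 60.0
    sampling_rate: float = 2048.0
    grid_rows: int = 8
    grid_cols: int = 8
    fasciculation_rate_per_min: float = 40.0
    refractory_ms: float = 10.0
    n_voluntary_units: int = 0
    voluntary_rate_hz: float = 7.0
    voluntary_isi_cv: float = 0.12
    voluntary_epochs: tuple = ()           # [start, end) pairs in seconds
    multiplet_rate_per_min: float = 0.0
    multiplet_gap_ms: float = 30.0
    spike_amp_uv: float = 300.0
    spike_channel_footprint: int = 10
    noise_sd_uv: float = 3.0
    line_noise_uv: float = 2.0
    drift_uv: float = 15.0
    dead_channels: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate <= 0:
            raise ConfigurationError("duration and sampling rate must be positive")
        for r in ("fasciculation_rate_per_min", "multiplet_rate_per_min",
                  "noise_sd_uv", "line_noise_uv", "drift_uv"):
            if getattr(self, r) < 0:
                raise ConfigurationError(f"{r} must be >= 0")
        if not 4.0 <= self.voluntary_rate_hz <= 12.0:
            raise ConfigurationError("voluntary_rate_hz must lie in [4, 12] Hz")
        if not 0 < self.multiplet_gap_ms < 50.0:
            raise ConfigurationError("multiplet_gap_ms must lie in (0, 50) ms")
        if self.spike_channel_footprint < 10:
            raise ConfigurationError("spike_channel_footprint must be >= 10 channels")
        for s, e in self.voluntary_epochs:
            if not 0 <= s < e <= self.duration_s:
                raise ConfigurationError(f"voluntary epoch [{s}, {e}) outside recording")


@dataclass
class SpikeRecord:
    time_s: float
    unit_id: int
    kind: str  # fasciculation | voluntary | multiplet_secondary


@dataclass
class SynthGroundTruth:
    """Everything the generator knows: the answer key for the pipeline."""

    spikes: list[SpikeRecord]
    voluntary_epochs: tuple
    noise_sd_uv: float
    line_noise_uv: float
    drift_uv: float
    dead_channels: tuple
    unit_epicentres: dict = field(default_factory=dict)

    def spike_times(self, kind: str | None = None) -> np.ndarray:
        return np.array(sorted(
            s.time_s for s in self.spikes if kind is None or s.kind == kind
        ))


# ---------------------------------------------------------------------------
# spike-time processes
# ---------------------------------------------------------------------------

def draw_fasciculation_times(
    rate_per_min: float, duration_s: float, refractory_ms: float, rng
) -> np.ndarray:
    """Homogeneous Poisson spike times thinned by the refractory period."""
    rate = rate_per_min / 60.0
    n = rng.poisson(rate * duration_s)
    t = np.sort(rng.uniform(0.0, duration_s, n))
    refr = refractory_ms / 1000.0
    kept, last = [], -np.inf
    for ti in t:
        if ti - last >= refr:
            kept.append(ti)
            last = ti
    return np.array(kept)


def draw_voluntary_train(
    epoch: tuple[float, float], rate_hz: float, isi_cv: float,
    refractory_ms: float, rng, max_isi_s: float = 0.249,
) -> np.ndarray:
    """Regular-firing spike times inside one epoch.

    ISIs are ``rate⁻¹ (1 + cv·N(0,1))`` clipped to [refractory, 249 ms] so
    the generated train always satisfies the < 250 ms train definition.
    """
    start, end = epoch
    base = 1.0 / rate_hz
    t = start + rng.uniform(0.0, base / 2)
    times = []
    while t < end:
        times.append(t)
        isi = base * (1.0 + isi_cv * rng.standard_normal())
        t += float(np.clip(isi, refractory_ms / 1000.0, max_isi_s))
    return np.array(times)


# ---------------------------------------------------------------------------
# waveform and spatial model
# ---------------------------------------------------------------------------

def spike_template(sampling_rate: float) -> np.ndarray:
    """Triphasic Hanning-windowed waveform, ~15 ms, peak amplitude 1."""
    n = max(int(round(SPIKE_TEMPLATE_MS / 1000.0 * sampling_rate)), 7)
    u = np.linspace(0.0, 1.0, n, endpoint=False)
    # sqrt-Hanning taper keeps the two side lobes near half the main lobe,
    # so both polarities of a potential cross their screening thresholds
    w = np.sqrt(np.hanning(n)) * np.sin(3.0 * np.pi * u)
    return w / np.abs(w).max()


def spatial_weights(
    positions: dict[int, tuple[int, int]], epicentre: tuple[float, float]
) -> np.ndarray:
    """Exponential amplitude decay with grid distance from the epicentre."""
    r0, c0 = epicentre
    ids = sorted(positions)
    d = np.array([np.hypot(positions[c][0] - r0, positions[c][1] - c0) for c in ids])
    return np.exp(-d / SPATIAL_DECAY_CHANNELS)


def _draw_epicentre(rng, rows: int, cols: int) -> tuple[float, float]:
    # one electrode pitch of margin: on an 8x8 grid every interior epicentre
    # keeps >= 10 channels within the quarter-amplitude radius decay*ln(4),
    # while spreading spike energy over the whole grid rather than its centre
    m_r = min(1.0, (rows - 1) / 2.0)
    m_c = min(1.0, (cols - 1) / 2.0)
    return (rng.uniform(m_r, rows - 1 - m_r), rng.uniform(m_c, cols - 1 - m_c))


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_recording(params: SynthParams) -> tuple[GridRecording, SynthGroundTruth]:
    """Synthesize a grid recording and its ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    rows, cols = params.grid_rows, params.grid_cols
    n_samples = int(round(params.duration_s * fs))
    n_channels = rows * cols
    positions = default_grid_positions(rows, cols)
    signal = np.zeros((n_samples, n_channels))
    template = spike_template(fs)
    peak_offset = int(np.argmax(np.abs(template)))

    spikes: list[SpikeRecord] = []
    epicentres: dict[int, tuple[float, float]] = {}
    unit_id = 0

    def add_spike(t, unit, kind):
        spikes.append(SpikeRecord(time_s=float(t), unit_id=unit, kind=kind))

    # fasciculations: one random epicentre per event (each its own unit)
    fasc = draw_fasciculation_times(
        params.fasciculation_rate_per_min, params.duration_s, params.refractory_ms, rng
    )
    placements = []  # (time, unit_id, amp_scale)
    for t in fasc:
        epicentres[unit_id] = _draw_epicentre(rng, rows, cols)
        add_spike(t, unit_id, "fasciculation")
        placements.append((t, unit_id))
        unit_id += 1

    # voluntary units: fixed epicentre per unit, regular firing in epochs
    for _ in range(params.n_voluntary_units):
        epicentres[unit_id] = _draw_epicentre(rng, rows, cols)
        for epoch in params.voluntary_epochs:
            for t in draw_voluntary_train(
                epoch, params.voluntary_rate_hz, params.voluntary_isi_cv,
                params.refractory_ms, rng,
            ):
                add_spike(t, unit_id, "voluntary")
                placements.append((t, unit_id))
        unit_id += 1

    # multiplets: parent + identical-morphology partner at a short gap
    if params.multiplet_rate_per_min > 0:
        parents = draw_fasciculation_times(
            params.multiplet_rate_per_min, params.duration_s, params.refractory_ms, rng
        )
        gap = params.multiplet_gap_ms / 1000.0
        for t in parents:
            epicentres[unit_id] = _draw_epicentre(rng, rows, cols)
            add_spike(t, unit_id, "fasciculation")
            placements.append((t, unit_id))
            if t + gap < params.duration_s:
                add_spike(t + gap, unit_id, "multiplet_secondary")
                placements.append((t + gap, unit_id))
            unit_id += 1

    # paint waveforms
    for t, unit in placements:
        amp = params.spike_amp_uv * rng.lognormal(0.0, AMP_LOGNORMAL_SIGMA)
        weights = spatial_weights(positions, epicentres[unit])
        i0 = int(round(t * fs)) - peak_offset
        a, b = max(i0, 0), min(i0 + len(template), n_samples)
        if b <= a:
            continue
        signal[a:b] += amp * np.outer(template[a - i0: b - i0], weights)

    # noise, line interference, drift
    tvec = np.arange(n_samples) / fs
    if params.noise_sd_uv > 0:
        signal += rng.normal(0.0, params.noise_sd_uv, size=signal.shape)
    if params.line_noise_uv > 0:
        phase = rng.uniform(0.0, 2 * np.pi)
        signal += params.line_noise_uv * np.sin(2 * np.pi * 50.0 * tvec + phase)[:, None]
    if params.drift_uv > 0:
        phases = rng.uniform(0.0, 2 * np.pi, size=n_channels)
        signal += params.drift_uv * np.sin(
            2 * np.pi * DRIFT_HZ * tvec[:, None] + phases[None, :]
        )
    for dc in params.dead_channels:
        signal[:, dc] = 0.0

    recording = GridRecording(
        signal=signal,
        sampling_rate=fs,
        grid_rows=rows,
        grid_cols=cols,
        channel_positions=positions,
        meta={"synthetic": True, "seed": params.seed},
    )
    truth = SynthGroundTruth(
        spikes=sorted(spikes, key=lambda s: s.time_s),
        voluntary_epochs=tuple(params.voluntary_epochs),
        noise_sd_uv=params.noise_sd_uv,
        line_noise_uv=params.line_noise_uv,
        drift_uv=params.drift_uv,
        dead_channels=tuple(params.dead_channels),
        unit_epicentres=epicentres,
    )
    return recording, truth


# ---------------------------------------------------------------------------
# fixture presets
# ---------------------------------------------------------------------------

PRESETS = ("relaxed", "partially_relaxed", "voluntary", "noisy", "mixed")


def preset_params(preset_name: str, duration_s: float = 60.0, seed: int = 0) -> SynthParams:
    """Parameters for the standard fixture categories.

    The categories mirror how resting EMG samples present in practice:
    fully relaxed, partially relaxed (a voluntary spell inside an
    otherwise relaxed recording), voluntarily active throughout, too noisy
    to analyse, and a mixed recording with multiplets.
    """
    base = SynthParams(duration_s=duration_s, seed=seed)
    if preset_name == "relaxed":
        return base
    if preset_name == "partially_relaxed":
        return replace(
            base, n_voluntary_units=1, voluntary_rate_hz=7.0,
            voluntary_epochs=((0.35 * duration_s, 0.60 * duration_s),),
        )
    if preset_name == "voluntary":
        return replace(
            base, n_voluntary_units=2, voluntary_rate_hz=8.0,
            voluntary_epochs=((0.0, duration_s),),
        )
    if preset_name == "noisy":
        return replace(base, noise_sd_uv=40.0)
    if preset_name == "mixed":
        return replace(
            base, n_voluntary_units=1, voluntary_rate_hz=8.0,
            voluntary_epochs=((0.30 * duration_s, 0.55 * duration_s),),
            multiplet_rate_per_min=6.0, noise_sd_uv=5.0,
        )
    raise ConfigurationError(f"unknown preset {preset_name!r}; choose from {PRESETS}")


def make_fixture_suite(
    preset_name: str, n: int = 1, duration_s: float = 60.0, base_seed: int = 0
) -> list[tuple[GridRecording, SynthGroundTruth]]:
    """Generate ``n`` seeded fixtures of one preset."""
    out = []
    for i in range(n):
        params = preset_params(preset_name, duration_s=duration_s, seed=base_seed + i)
        out.append(generate_recording(params))
    return out
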