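"""End-to-end pipeline: preprocess -> detect -> noisy-block exclusion ->
voluntary-activity exclusion -> summary.

Stage order is fixed: noise-based 5 s block exclusion runs before
voluntary-activity labelling, so artefact spikes cannot form spurious
trains; the voluntary stage only sees surviving included potentials.
Time accounting is exact: analysed + excluded(noise) + excluded(voluntary)
equals the recording duration, with voluntary exclusion credited only for
time not already removed as noisy.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import detect, preprocess, voluntary
from .config import PipelineConfig
from .metrics import fasciculation_frequency
from .recording import GridRecording


@dataclass
class RecordingSummary:
    """Headline outputs of one pipeline run."""

    time_analysed_min: float
    time_excluded_noise_min: float
    time_excluded_voluntary_min: float   # voluntary-activity exclusion
    n_potentials_included: int
    fasciculation_frequency_per_min: float | None
    median_noise_band_uv: float | None
    n_channels_excluded: int
    strategy_used: str
    rng_seed: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    summary: RecordingSummary
    recording: GridRecording            # preprocessed, surviving channels
    quality: object                     # channel QC DataFrame (or None)
    superchannel: detect.SuperChannel
    noise_blocks: list
    activity_blocks: list
    histogram: tuple                    # (counts, bin_edges_ms)

    def excluded_intervals(self) -> list[tuple[float, float]]:
        ints = [(b.start_s, b.end_s) for b in self.noise_blocks if b.excluded]
        ints += [(b.start_s, b.end_s) for b in self.activity_blocks if b.final_excluded]
        return merge_intervals(ints)


# ---------------------------------------------------------------------------
# interval arithmetic (half-open [start, end) intervals in seconds)
# ---------------------------------------------------------------------------

def merge_intervals(intervals) -> list[tuple[float, float]]:
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[list[float]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def total_length(intervals) -> float:
    return sum(e - s for s, e in merge_intervals(intervals))


def subtract_length(intervals, minus) -> float:
    """Length of ``intervals`` not covered by ``minus``."""
    a = merge_intervals(intervals)
    b = merge_intervals(minus)
    remaining = 0.0
    for s, e in a:
        cut = 0.0
        for bs, be in b:
            lo, hi = max(s, bs), min(e, be)
            if hi > lo:
                cut += hi - lo
        remaining += (e - s) - cut
    return remaining


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    recording: GridRecording,
    config: PipelineConfig | None = None,
    classifier: voluntary.TrainedClassifier | None = None,
) -> PipelineResult:
    """Run every stage on one recording; deterministic given the config seed."""
    config = config or PipelineConfig()
    config.validate()
    duration = recording.duration_s

    # --- preprocess -----------------------------------------------------
    rec = recording
    if config.common_average_reference:
        rec = preprocess.common_average_reference(rec)
    if config.perimeter_trim and rec.grid_rows >= 3 and rec.grid_cols >= 3:
        rec = preprocess.trim_to_central_grid(rec)
    quality = None
    n_excluded_channels = 0
    if rec.n_channels >= 8 and not config.qc_on_filtered:
        rec, quality = preprocess.exclude_bad_channels(rec, config)
    rec = preprocess.bandpass_notch(rec, config)
    if rec.n_channels >= 8 and config.qc_on_filtered:
        rec, quality = preprocess.exclude_bad_channels(rec, config)
    if quality is not None:
        n_excluded_channels = int(quality["excluded"].sum())

    # --- detect ---------------------------------------------------------
    events = detect.screen_potentials(rec, config)
    superchannel = detect.build_superchannel(rec, events, config)
    detect.annotate_noise_bands(rec, superchannel, config)
    med_noise = detect.median_noise(superchannel.potentials)
    for p in superchannel.potentials:
        detect.apply_inclusion_threshold(p, config)
    noise_blocks = detect.exclude_noisy_blocks(superchannel.potentials, duration, config)
    noise_intervals = [(b.start_s, b.end_s) for b in noise_blocks if b.excluded]

    # --- voluntary-activity exclusion -----------------------------------
    activity_blocks, activity_intervals = voluntary.apply_strategy(
        superchannel.potentials, duration, config, classifier=classifier
    )

    # --- accounting and readouts ----------------------------------------
    t_noise = total_length(noise_intervals)
    t_voluntary = subtract_length(activity_intervals, noise_intervals)
    t_analysed = duration - t_noise - t_voluntary
    included = [p for p in superchannel.potentials if p.included]
    freq = fasciculation_frequency(len(included), t_analysed / 60.0)
    excluded_epochs = merge_intervals(noise_intervals + activity_intervals)
    histogram = voluntary.interval_histogram(
        np.array([p.peak_time_s for p in included]),
        range_ms=config.histogram_range_ms,
        bin_ms=config.histogram_bin_ms,
        excluded_epochs=excluded_epochs,
    )
    summary = RecordingSummary(
        time_analysed_min=t_analysed / 60.0,
        time_excluded_noise_min=t_noise / 60.0,
        time_excluded_voluntary_min=t_voluntary / 60.0,
        n_potentials_included=len(included),
        fasciculation_frequency_per_min=freq,
        median_noise_band_uv=med_noise,
        n_channels_excluded=n_excluded_channels,
        strategy_used=config.strategy,
        rng_seed=config.rng_seed,
    )
    return PipelineResult(
        summary=summary,
        recording=rec,
        quality=quality,
        superchannel=superchannel,
        noise_blocks=noise_blocks,
        activity_blocks=activity_blocks,
        histogram=histogram,
    )
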