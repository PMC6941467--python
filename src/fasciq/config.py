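"""Pipeline configuration.

Every tunable threshold of the pipeline lives here with its published
default: the 20–500 Hz analysis band with 50 Hz notch, the 2 % extreme
amplitude occupancy of the initial screen, the noise-responsive inclusion
threshold factor (AT_inc = 8 x local noise band), the 100 μV exclusion
threshold driving 5 s noisy-block rejection, the ≥4-potential / <250 ms
definition of a voluntary train, the 84–250 ms (4–12 Hz) feature band and
the 30-tree bagged classifier with 5-fold cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import ConfigurationError

STRATEGIES = ("0", "1A", "1B", "2")


@dataclass
class PipelineConfig:
    # temporal filtering
    bandpass_low_hz: float = 20.0
    bandpass_high_hz: float = 500.0
    notch_hz: float = 50.0
    notch_q: float = 30.0
    common_average_reference: bool = False

    # channel handling
    perimeter_trim: bool = True
    qc_on_filtered: bool = False  # channel QC runs on the raw signal by default
    null_channel_sd_uv: float = 0.01

    # potential screening / thresholding
    extreme_occupancy_fraction: float = 0.02
    occupancy_positive_share: float = 0.5  # 2% budget split 1% positive + 1% negative
    event_prominence_factor: float = 1.5   # cluster p2t must exceed this x threshold span
    merge_pad_ms: float = 10.0
    noise_window_s: float = 1.0
    at_inc_noise_factor: float = 8.0
    at_exc_uv: float = 100.0
    noise_block_s: float = 5.0

    # voluntary-activity identification
    strategy: str = "0"
    block_sensitive_s: float = 10.0
    block_specific_s: float = 1.0
    train_min_potentials: int = 4
    train_max_isi_ms: float = 250.0
    feature_band_ms: tuple[float, float] = (84.0, 250.0)
    n_trees: int = 30
    cv_folds: int = 5

    # readouts
    histogram_range_ms: float = 400.0
    histogram_bin_ms: float = 10.0
    peak_ratio_k: float = 3.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.feature_band_ms = tuple(self.feature_band_ms)
        self.validate()

    def validate(self) -> None:
        positive = [
            "bandpass_low_hz", "bandpass_high_hz", "notch_hz", "notch_q",
            "null_channel_sd_uv", "extreme_occupancy_fraction",
            "event_prominence_factor", "merge_pad_ms",
            "noise_window_s", "at_inc_noise_factor", "at_exc_uv", "noise_block_s",
            "block_sensitive_s", "block_specific_s", "train_min_potentials",
            "train_max_isi_ms", "n_trees", "cv_folds", "histogram_range_ms",
            "histogram_bin_ms", "peak_ratio_k",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not 0 < self.occupancy_positive_share < 1:
            raise ConfigurationError("occupancy_positive_share must lie in (0, 1)")
        if self.bandpass_low_hz >= self.bandpass_high_hz:
            raise ConfigurationError("bandpass_low_hz must be < bandpass_high_hz")
        lo, hi = self.feature_band_ms
        if lo <= 0 or lo >= hi:
            raise ConfigurationError("feature_band_ms must satisfy 0 < lower < upper")
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(f"strategy must be one of {STRATEGIES}")

    # -- on-disk representation ------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_band_ms"] = list(self.feature_band_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))
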