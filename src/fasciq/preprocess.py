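"""Temporal filtering, perimeter trimming and automated bad-channel exclusion.

The filter chain is a 4th-order Butterworth band-pass (20–500 Hz by
default) plus a narrow IIR notch at the mains frequency, both applied
forward-backward so spike times are not shifted.  Channel quality control
follows a two-metric outlier screen: per channel, the area under the
one-sided FFT magnitude spectrum inside the analysis band and the
peak-to-peak amplitude range are computed; channels falling outside
mean ± 1.96·SD across channels on either metric are excluded, as are
null channels (flat signal from absent electrode contact).
"""

from __future__ import annotations

import pandas as pd
import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .errors import ConfigurationError, UnanalysableRecordingError
from .recording import GridRecording

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


def bandpass_notch(recording: GridRecording, config: PipelineConfig) -> GridRecording:
    """Zero-phase band-pass + notch filtering of every channel."""
    fs = recording.sampling_rate
    if fs <= 2 * config.bandpass_high_hz:
        raise ConfigurationError(
            f"sampling rate {fs} Hz too low for a {config.bandpass_high_hz} Hz band edge"
        )
    sos = sps.butter(
        4, [config.bandpass_low_hz, config.bandpass_high_hz],
        btype="bandpass", fs=fs, output="sos",
    )
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=0)
    b, a = sps.iirnotch(config.notch_hz, Q=config.notch_q, fs=fs)
    filtered = sps.filtfilt(b, a, filtered, axis=0)
    return recording.with_signal(filtered)


def common_average_reference(recording: GridRecording) -> GridRecording:
    """Re-reference every channel against the mean of all channels."""
    sig = recording.signal
    return recording.with_signal(sig - sig.mean(axis=1, keepdims=True))


def trim_to_central_grid(recording: GridRecording) -> GridRecording:
    """Discard the outer perimeter of grid channels.

    The outermost electrode ring suffers most from poor skin contact; for
    an 8x8 grid the central 6x6 block of 36 channels survives.
    """
    rows, cols = recording.grid_rows, recording.grid_cols
    if rows < 3 or cols < 3:
        raise ConfigurationError("perimeter trim requires a grid of at least 3x3")
    keep = [
        cid for cid, (r, c) in recording.channel_positions.items()
        if 1 <= r <= rows - 2 and 1 <= c <= cols - 2
    ]
    if not keep:
        raise UnanalysableRecordingError("no central channels present after trim")
    return recording.select_channels(keep)


def channel_quality(recording: GridRecording, config: PipelineConfig) -> pd.DataFrame:
    """Per-channel quality metrics and exclusion decisions.

    Returns a data frame with one row per channel: ``channel``, ``row``,
    ``col``, ``fft_auc``, ``amplitude_range_uv``, ``excluded``, ``reason``
    (one of ``null_channel``, ``fft_auc_outlier``, ``range_outlier`` or
    empty).
    """
    sig = recording.signal
    fs = recording.sampling_rate
    freqs = np.fft.rfftfreq(sig.shape[0], d=1.0 / fs)
    band = (freqs >= config.bandpass_low_hz) & (freqs <= config.bandpass_high_hz)
    spectrum = np.abs(np.fft.rfft(sig, axis=0))
    fft_auc = spectrum[band].sum(axis=0)
    amp_range = sig.max(axis=0) - sig.min(axis=0)
    sd = sig.std(axis=0)

    reasons = np.array([""] * recording.n_channels, dtype=object)
    reasons[sd < config.null_channel_sd_uv] = "null_channel"
    for metric, label in ((fft_auc, "fft_auc_outlier"), (amp_range, "range_outlier")):
        mu, sigma = metric.mean(), metric.std(ddof=1)
        if sigma > 0:
            outlier = np.abs(metric - mu) > Z_95 * sigma
            fresh = outlier & (reasons == "")
            reasons[fresh] = label

    ids = recording.channel_ids
    return pd.DataFrame(
        {
            "channel": ids,
            "row": [recording.channel_positions[c][0] for c in ids],
            "col": [recording.channel_positions[c][1] for c in ids],
            "fft_auc": fft_auc,
            "amplitude_range_uv": amp_range,
            "excluded": reasons != "",
            "reason": reasons,
        }
    )


def exclude_bad_channels(
    recording: GridRecording, config: PipelineConfig
) -> tuple[GridRecording, pd.DataFrame]:
    """Drop channels flagged by :func:`channel_quality`.

    Raises :class:`UnanalysableRecordingError` when nothing survives,
    mirroring recordings too poor to analyse at all.
    """
    if recording.n_channels < 8:
        raise ConfigurationError("channel quality control needs at least 8 channels")
    report = channel_quality(recording, config)
    keep = report.loc[~report["excluded"], "channel"].tolist()
    if not keep:
        raise UnanalysableRecordingError("recording unanalysable: all channels excluded")
    return recording.select_channels(keep), report
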