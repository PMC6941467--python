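"""Noise-responsive detection of candidate motor-unit potentials.

Stages, in pipeline order:

1. **Extreme-amplitude screen** (:func:`screen_potentials`) — per channel,
   amplitude thresholds are set at the quantiles leaving at most the
   configured occupancy (2 % by default, split half positive half negative)
   beyond them.  Threshold-crossing runs within a 10 ms gap are clustered;
   a cluster qualifies as a candidate event only when it contains both a
   supra-positive and a sub-negative run, i.e. it exhibits the peak *and*
   trough of a motor-unit potential.  Isolated single-polarity noise
   crossings therefore do not become events.
2. **Super-channel assembly** (:func:`build_superchannel`) — events that
   overlap in time across channels (after 10 ms padding) are merged into
   one :class:`Potential` sourced from the channel with the largest
   peak-trough amplitude inside the merged span, collapsing the grid into
   a single-dimensional trace of candidate potentials.
3. **Noise bands and inclusion threshold** — each potential's local noise
   band is mean(positive) − mean(negative) amplitude over the one-second
   windows flanking its span (other potentials' spans masked out); the
   amplitude inclusion threshold is 8x that noise band, and a potential is
   included only when its peak-trough amplitude reaches it.
4. **Noisy-block exclusion** (:func:`exclude_noisy_blocks`) — the recording
   is tiled into 5 s blocks; a block is discarded when more than half of
   its potentials have inclusion thresholds above the 100 μV exclusion
   threshold, or any single one exceeds double it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .recording import GridRecording

logger = logging.getLogger(__name__)


@dataclass
class Potential:
    """One candidate motor-unit event on the super-channel."""

    peak_time_s: float
    span: tuple[int, int]          # half-open sample interval
    channel: int                   # source channel id (largest peak-trough)
    peak_uv: float
    trough_uv: float
    p2t_uv: float
    noise_band_uv: float | None = None
    at_inc_uv: float | None = None
    included: bool = True
    exclusion_reason: str | None = None  # below_at_inc | noisy_block | voluntary

    def exclude(self, reason: str) -> None:
        if self.included:
            self.included = False
            self.exclusion_reason = reason


@dataclass
class SuperChannel:
    """Time-ordered, non-overlapping candidate potentials for a recording."""

    potentials: list[Potential]
    duration_s: float

    def times(self, included_only: bool = False) -> np.ndarray:
        return np.array(
            [p.peak_time_s for p in self.potentials if p.included or not included_only]
        )


@dataclass
class NoiseBlock:
    """A fixed 5 s window with its noisy-block exclusion state."""

    index: int
    start_s: float
    end_s: float
    excluded: bool = False
    rule_fired: str | None = None  # half_above_atexc | any_above_double
    n_potentials: int = 0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# extreme-amplitude screening
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean vector."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def screen_channel(x: np.ndarray, fs: float, config: PipelineConfig) -> list[tuple[int, int]]:
    """Candidate event spans on one channel.

    Thresholds sit at the ``1 - f*share`` and ``f*(1-share)`` amplitude
    quantiles (f = extreme occupancy fraction), so strictly supra-threshold
    occupancy cannot exceed f.  Runs beyond either threshold are clustered
    within the merge gap; a cluster becomes an event when it contains both
    polarities and its peak-trough amplitude clearly exceeds the span
    between the two thresholds (isolated tail samples of the background
    noise fail both conditions, a genuine biphasic potential passes both).
    """
    if np.ptp(x) == 0.0:
        logger.warning("constant channel: no events screened")
        return []
    f = config.extreme_occupancy_fraction
    share = config.occupancy_positive_share
    # outward-rounded quantiles guarantee strict crossings stay within budget
    hi = np.quantile(x, 1.0 - f * share, method="higher")
    lo = np.quantile(x, f * (1.0 - share), method="lower")
    prominence = config.event_prominence_factor * (hi - lo)
    gap = int(round(config.merge_pad_ms / 1000.0 * fs))
    tagged = [(s, e, +1) for s, e in _runs(x > hi)] + [(s, e, -1) for s, e in _runs(x < lo)]
    tagged.sort()
    events: list[tuple[int, int]] = []

    def close(s, e, polarities):
        if len(polarities) == 2 and np.ptp(x[s:e]) >= prominence:
            events.append((s, e))

    cur_s = cur_e = None
    polarities: set[int] = set()
    for s, e, pol in tagged:
        if cur_e is not None and s - cur_e <= gap:
            cur_e = max(cur_e, e)
            polarities.add(pol)
        else:
            if cur_s is not None:
                close(cur_s, cur_e, polarities)
            cur_s, cur_e, polarities = s, e, {pol}
    if cur_s is not None:
        close(cur_s, cur_e, polarities)
    return events


def screen_potentials(
    recording: GridRecording, config: PipelineConfig
) -> dict[int, list[tuple[int, int]]]:
    """Per-channel candidate event spans (sample indices)."""
    return {
        cid: screen_channel(recording.channel_signal(cid), recording.sampling_rate, config)
        for cid in recording.channel_ids
    }


# ---------------------------------------------------------------------------
# super-channel
# ---------------------------------------------------------------------------

def build_superchannel(
    recording: GridRecording,
    events: dict[int, list[tuple[int, int]]],
    config: PipelineConfig,
) -> SuperChannel:
    """Merge per-channel events into a single ordered potential list.

    A potential seen on several channels produces near-simultaneous events;
    they are grouped by amplitude-seeded peak matching: events are visited
    in order of decreasing peak-trough amplitude, each either founding a
    new potential or being absorbed by the existing one whose peak lies
    within the merge window (10 ms).  Seeding by amplitude rather than by
    transitive span overlap keeps dense stretches of candidates from
    chaining into one giant event, and makes the result independent of
    channel processing order.  The merged potential is sourced from the
    contributing channel with the greatest peak-trough amplitude within
    the merged span; spans are clipped at inter-peak midpoints so they
    never overlap.
    """
    fs = recording.sampling_rate
    pad = int(round(config.merge_pad_ms / 1000.0 * fs))

    items = []  # (p2t, start, end, cid, peak_sample)
    for cid, spans in events.items():
        x = recording.channel_signal(cid)
        for s, e in spans:
            seg = x[s:e]
            items.append((float(seg.max() - seg.min()), s, e, cid, s + int(np.argmax(np.abs(seg)))))
    # strongest first; start/channel break ties deterministically
    items.sort(key=lambda it: (-it[0], it[1], it[3]))

    import bisect

    seed_peaks: list[int] = []          # kept sorted by seed peak sample
    clusters: list[list[tuple]] = []    # parallel to seed order of insertion
    order: list[int] = []               # cluster index sorted like seed_peaks

    for it in items:
        peak = it[4]
        j = bisect.bisect_left(seed_peaks, peak)
        best, best_d = None, pad + 1
        for k in (j - 1, j):
            if 0 <= k < len(seed_peaks) and abs(seed_peaks[k] - peak) < best_d:
                best, best_d = k, abs(seed_peaks[k] - peak)
        if best is not None and best_d <= pad:
            clusters[order[best]].append(it)
        else:
            seed_peaks.insert(j, peak)
            order.insert(j, len(clusters))
            clusters.append([it])

    # hull spans in seed-peak order, clipped at inter-seed midpoints so the
    # resulting potentials never overlap (seed peaks are > pad apart)
    hulls = []
    for j, k in enumerate(order):
        members = clusters[k]
        hulls.append([
            min(s for _, s, _, _, _ in members),
            max(e for _, _, e, _, _ in members),
            seed_peaks[j],
            members,
        ])
    for a, b in zip(hulls, hulls[1:]):
        if a[1] > b[0]:
            mid = (a[2] + b[2] + 1) // 2
            a[1] = min(a[1], mid)
            b[0] = max(b[0], mid)

    potentials = [
        _merge_cluster(recording, start, end, members)
        for start, end, _, members in hulls
    ]
    return SuperChannel(potentials=potentials, duration_s=recording.duration_s)


def _merge_cluster(recording: GridRecording, start: int, end: int, members) -> Potential:
    fs = recording.sampling_rate
    best_cid, best_p2t = None, -np.inf
    for cid in sorted({cid for _, _, _, cid, _ in members}):
        seg = recording.channel_signal(cid)[start:end]
        p2t = float(seg.max() - seg.min())
        if p2t > best_p2t:
            best_cid, best_p2t = cid, p2t
    seg = recording.channel_signal(best_cid)[start:end]
    peak_idx = int(np.argmax(np.abs(seg)))
    return Potential(
        peak_time_s=(start + peak_idx) / fs,
        span=(start, end),
        channel=best_cid,
        peak_uv=float(seg.max()),
        trough_uv=float(seg.min()),
        p2t_uv=best_p2t,
    )


# ---------------------------------------------------------------------------
# noise bands and thresholds
# ---------------------------------------------------------------------------

def _occupancy_mask(n_samples: int, potentials: list[Potential]) -> np.ndarray:
    mask = np.zeros(n_samples, dtype=bool)
    for p in potentials:
        mask[p.span[0]: p.span[1]] = True
    return mask


def _noise_band_from_values(vals: np.ndarray) -> float | None:
    if vals.size == 0:
        return None
    pos = vals[vals > 0]
    neg = vals[vals < 0]
    mean_pos = float(pos.mean()) if pos.size else 0.0
    mean_neg = float(neg.mean()) if neg.size else 0.0
    return mean_pos - mean_neg


def compute_noise_band(
    recording: GridRecording,
    potential: Potential,
    all_potentials: list[Potential],
    config: PipelineConfig,
) -> float | None:
    """Local noise band of one potential, in μV.

    mean(positive) − mean(negative) amplitude on the source channel over
    the one-second windows flanking the span, truncated at recording edges,
    with samples inside any other potential's span removed.  An empty sign
    class contributes 0; a completely empty window yields ``None``.
    """
    occupied = _occupancy_mask(recording.n_samples, [q for q in all_potentials if q is not potential])
    return _noise_band_one(recording, potential, occupied, config)


def _noise_band_one(recording, potential, occupied, config) -> float | None:
    fs = recording.sampling_rate
    w = int(round(config.noise_window_s * fs))
    s, e = potential.span
    x = recording.channel_signal(potential.channel)
    before = np.arange(max(0, s - w), s)
    after = np.arange(e, min(recording.n_samples, e + w))
    idx = np.concatenate([before, after])
    idx = idx[~occupied[idx]] if idx.size else idx
    return _noise_band_from_values(x[idx])


def annotate_noise_bands(
    recording: GridRecording, superchannel: SuperChannel, config: PipelineConfig
) -> None:
    """Fill ``noise_band_uv`` for every potential (in place)."""
    occupied = _occupancy_mask(recording.n_samples, superchannel.potentials)
    for p in superchannel.potentials:
        s, e = p.span
        occupied[s:e] = False          # own span never flanks itself
        p.noise_band_uv = _noise_band_one(recording, p, occupied, config)
        occupied[s:e] = True


def median_noise(potentials: list[Potential]) -> float | None:
    """Median of the defined per-potential noise bands (μV).

    The median is robust against the occasional large positive outlier
    that would distort a mean.  ``None`` when no noise band is defined.
    """
    bands = [p.noise_band_uv for p in potentials if p.noise_band_uv is not None]
    if not bands:
        return None
    return float(np.median(bands))


def apply_inclusion_threshold(potential: Potential, config: PipelineConfig) -> bool:
    """Noise-responsive inclusion: AT_inc = factor x noise band.

    A potential is included when its peak-trough amplitude reaches AT_inc.
    Potentials with an undefined noise band cannot be judged and are
    excluded as noisy.
    """
    if potential.noise_band_uv is None:
        potential.exclude("noisy_block")
        return False
    potential.at_inc_uv = config.at_inc_noise_factor * potential.noise_band_uv
    if potential.p2t_uv < potential.at_inc_uv:
        potential.exclude("below_at_inc")
    return potential.included


def exclude_noisy_blocks(
    potentials: list[Potential], duration_s: float, config: PipelineConfig
) -> list[NoiseBlock]:
    """Tile the recording into 5 s blocks and reject the noisy ones.

    A block is excluded if (a) AT_inc exceeded AT_exc for more than half of
    its potentials, or (b) at least one AT_inc exceeded double AT_exc.
    Excluded blocks drop their potentials; the final partial block is
    judged by the same rules but only its actual duration counts.
    """
    block_s = config.noise_block_s
    n_blocks = int(np.ceil(duration_s / block_s)) if duration_s > 0 else 0
    blocks = []
    for i in range(n_blocks):
        start = i * block_s
        end = min((i + 1) * block_s, duration_s)
        members = [
            p for p in potentials
            if start <= p.peak_time_s < end and p.at_inc_uv is not None
        ]
        block = NoiseBlock(index=i, start_s=start, end_s=end, n_potentials=len(members))
        if members:
            n_over = sum(p.at_inc_uv > config.at_exc_uv for p in members)
            if n_over > len(members) / 2:
                block.excluded, block.rule_fired = True, "half_above_atexc"
            elif any(p.at_inc_uv > 2 * config.at_exc_uv for p in members):
                block.excluded, block.rule_fired = True, "any_above_double"
        if block.excluded:
            for p in members:
                p.exclude("noisy_block")
        blocks.append(block)
    return blocks
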