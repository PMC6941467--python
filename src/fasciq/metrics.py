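"""Summary statistics, ground-truth evaluation, and report assembly."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DataError


@dataclass
class DetectionEvaluation:
    """Block-level confusion counts against ground truth."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_blocks(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity_pct(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def specificity_pct(self) -> float:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else float("nan")

    @property
    def ppv_pct(self) -> float:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def npv_pct(self) -> float:
        d = self.tn + self.fn
        return 100.0 * self.tn / d if d else float("nan")


def fasciculation_frequency(n_included: int, analysed_time_min: float) -> float | None:
    """Included potentials per analysed minute; ``None`` when no time remains."""
    if analysed_time_min <= 0:
        return None
    return n_included / analysed_time_min


def evaluate_blocks(blocks, truth_voluntary_times, min_count: int = 4) -> DetectionEvaluation:
    """Compare block labelling with generator ground truth.

    A block is truth-voluntary iff it contains at least ``min_count``
    ground-truth voluntary spikes (the same >= 4 definition the detector
    uses); the prediction is the block's ``flagged_voluntary``.
    """
    if not blocks:
        raise DataError("no blocks to evaluate")
    t = np.sort(np.asarray(truth_voluntary_times, dtype=float))
    tp = tn = fp = fn = 0
    for b in blocks:
        n_truth = int(np.sum((t >= b.start_s) & (t < b.end_s)))
        truth = n_truth >= min_count
        pred = bool(b.flagged_voluntary)
        if truth and pred:
            tp += 1
        elif truth:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    return DetectionEvaluation(tp=tp, tn=tn, fp=fp, fn=fn)


def median_evaluation(evaluations) -> dict:
    """Per-recording-median sensitivity/specificity across an ensemble.

    Mirrors evaluating each sample recording on its own and taking the
    median, which is robust to the occasional recording with few
    evaluable blocks.  NaNs (no positive or no negative blocks in a
    recording) are ignored per metric.
    """
    def med(vals):
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.median(vals)) if vals else float("nan")

    return {
        "sensitivity_pct": med([e.sensitivity_pct for e in evaluations]),
        "specificity_pct": med([e.specificity_pct for e in evaluations]),
        "ppv_pct": med([e.ppv_pct for e in evaluations]),
        "npv_pct": med([e.npv_pct for e in evaluations]),
        "n_recordings": len(list(evaluations)),
    }


def pooled_evaluation(evaluations) -> DetectionEvaluation:
    """Sum confusion counts over an ensemble before computing rates."""
    evaluations = list(evaluations)
    return DetectionEvaluation(
        tp=sum(e.tp for e in evaluations),
        tn=sum(e.tn for e in evaluations),
        fp=sum(e.fp for e in evaluations),
        fn=sum(e.fn for e in evaluations),
    )


def correlate_quality(summaries) -> pd.DataFrame:
    """OLS r² (and slope-test p) of frequency against data-quality readouts.

    One row per readout: median noise band and excluded-channel count.
    """
    rows = []
    recs = list(summaries)
    if len(recs) < 3:
        raise DataError("need at least 3 summaries to correlate")
    if len(recs) == 3:
        warnings.warn("correlation on 3 points is fragile", stacklevel=2)
    freq = np.array([s.fasciculation_frequency_per_min for s in recs], dtype=float)
    for name, attr in (
        ("median_noise_band_uv", "median_noise_band_uv"),
        ("n_channels_excluded", "n_channels_excluded"),
    ):
        x = np.array([getattr(s, attr) for s in recs], dtype=float)
        ok = np.isfinite(x) & np.isfinite(freq)
        if ok.sum() < 3 or np.ptp(x[ok]) == 0:
            rows.append({"readout": name, "r2": float("nan"), "p": float("nan"),
                         "slope": float("nan"), "n": int(ok.sum())})
            continue
        res = sstats.linregress(x[ok], freq[ok])
        rows.append({"readout": name, "r2": res.rvalue ** 2, "p": res.pvalue,
                     "slope": res.slope, "n": int(ok.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

def potentials_frame(potentials) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_time_s": [p.peak_time_s for p in potentials],
            "channel": [p.channel for p in potentials],
            "peak_uv": [p.peak_uv for p in potentials],
            "trough_uv": [p.trough_uv for p in potentials],
            "p2t_uv": [p.p2t_uv for p in potentials],
            "noise_band_uv": [p.noise_band_uv for p in potentials],
            "at_inc_uv": [p.at_inc_uv for p in potentials],
            "included": [p.included for p in potentials],
            "exclusion_reason": [p.exclusion_reason or "" for p in potentials],
        }
    )


def noise_blocks_frame(blocks) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": [b.index for b in blocks],
            "start_s": [b.start_s for b in blocks],
            "end_s": [b.end_s for b in blocks],
            "n_potentials": [b.n_potentials for b in blocks],
            "excluded": [b.excluded for b in blocks],
            "rule_fired": [b.rule_fired or "" for b in blocks],
        }
    )


def activity_blocks_frame(blocks) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [b.start_s for b in blocks],
            "end_s": [b.end_s for b in blocks],
            "n_potentials": [b.n_potentials for b in blocks],
            "flagged_voluntary": [b.flagged_voluntary for b in blocks],
            "classifier_prob": [b.classifier_prob for b in blocks],
            "final_excluded": [b.final_excluded for b in blocks],
        }
    )


def histogram_frame(counts, edges) -> pd.DataFrame:
    return pd.DataFrame(
        {"bin_start_ms": edges[:-1], "bin_end_ms": edges[1:], "count": counts}
    )


def build_report(result, outdir) -> dict:
    """Write the report bundle (CSV tables + figures) for one pipeline run.

    Emits the run summary, the per-potential table, both block tables, the
    interval histogram, a potential timeline figure with excluded epochs
    shaded, and the histogram figure.  Regeneration from the same result
    is byte-identical for the CSVs.  Returns the mapping of artifact name
    to path.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    summary_df = pd.DataFrame([result.summary.to_dict()])
    tables = {
        "summary": summary_df,
        "potentials": potentials_frame(result.superchannel.potentials),
        "noise_blocks": noise_blocks_frame(result.noise_blocks),
        "activity_blocks": activity_blocks_frame(result.activity_blocks),
        "histogram": histogram_frame(*result.histogram),
    }
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        paths[name] = p

    # timeline: included potentials as ticks, excluded epochs shaded
    fig, ax = plt.subplots(figsize=(10, 2.2))
    inc = [p.peak_time_s for p in result.superchannel.potentials if p.included]
    exc = [p.peak_time_s for p in result.superchannel.potentials if not p.included]
    ax.eventplot([inc], colors="tab:green", lineoffsets=1.0, linelengths=0.8)
    if exc:
        ax.eventplot([exc], colors="tab:orange", lineoffsets=0.0, linelengths=0.8)
    for s, e in result.excluded_intervals():
        ax.axvspan(s, e, color="grey", alpha=0.3, lw=0)
    ax.set_xlim(0, result.superchannel.duration_s)
    ax.set_yticks([0, 1], ["excluded", "included"])
    ax.set_xlabel("time (s)")
    fig.tight_layout()
    p = outdir / "timeline.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["timeline"] = p

    counts, edges = result.histogram
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", color="tab:blue")
    ax.set_xlabel("inter-potential interval (ms)")
    ax.set_ylabel("count")
    fig.tight_layout()
    p = outdir / "histogram.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["histogram_fig"] = p
    return paths
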