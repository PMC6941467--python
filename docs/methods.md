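# Methods

## Background and scope

Fasciculations — involuntary discharges of single motor units — are an early
and persistent feature of amyotrophic lateral sclerosis. On high-density
surface EMG (an 8×8 electrode grid sampled at 2048 Hz per channel) they
appear as brief multi-channel potentials firing as a Poisson process, so
their inter-spike intervals are exponential. Two error sources dominate
automated quantification of the *fasciculation frequency* (included
potentials per analysable minute): recording noise, and voluntary motor-unit
firing, which is regular at 4–12 Hz and would otherwise be counted as
fasciculation activity at a far higher rate. This package implements the
full quantification pipeline — noise-responsive detection, noisy-block
exclusion, voluntary-activity identification and exclusion — plus a seeded
synthetic grid-EMG generator so every stage can be validated against known
ground truth without patient data.

## Pipeline

Stages run in a fixed order; all timestamps are seconds from recording
start, sample indices are 0-based, intervals are half-open `[start, end)`.

1. **Filtering.** 4th-order Butterworth band-pass 20–500 Hz plus an IIR
   notch (Q = 30) at 50 Hz, both applied forward–backward (zero phase, so
   spike times are not shifted). The band edges and mains frequency are
   configurable. An optional common-average re-reference is off by default:
   grid amplifiers already reference against the average of connected
   inputs, and re-applying it to an exported signal is of unclear benefit.
2. **Perimeter trim.** The outer electrode ring suffers most from poor
   skin contact and is discarded; an 8×8 grid keeps its central 6×6 = 36
   channels.
3. **Channel quality control** (on the unfiltered signal, so baseline
   drift remains detectable; a config switch moves it after filtering).
   Two per-channel metrics: the sum of the one-sided FFT magnitude
   spectrum over the analysis band, and the amplitude range. A channel is
   excluded when either metric falls outside mean ± 1.96 SD across
   channels (single pass, sample SD), or when it is null (SD < 0.01 μV,
   i.e. no electrode contact). Drift screening is subsumed by the FFT
   metric. If nothing survives, the recording is unanalysable.
4. **Extreme-amplitude screen.** Per channel, a positive threshold at the
   `1 − f/2` amplitude quantile and a negative threshold at the `f/2`
   quantile, with `f = 0.02` (the 2 % occupancy budget split half/half;
   quantiles are rounded outward so strict crossings provably respect the
   budget). Threshold-crossing runs within a 10 ms gap form clusters; a
   cluster is a candidate event only if it (a) contains both a
   supra-positive and a sub-negative run — the peak *and* trough of a
   motor-unit potential — and (b) has peak-trough amplitude at least
   1.5× the span between the two thresholds. Condition (b) rejects chance
   pairings of opposite tail samples of the background noise (which would
   otherwise occur hundreds of times per minute) while being strictly
   weaker, on noise-dominated channels, than the final 8×-noise inclusion
   threshold — so it cannot cost a potential that would have been
   included.
5. **Super-channel assembly.** Events are grouped across channels by
   amplitude-seeded peak matching: events are visited strongest-first;
   each either founds a potential or is absorbed by the potential whose
   seed peak lies within 10 ms. Grouping by seed peaks rather than by
   transitive span overlap keeps dense candidate stretches from chaining
   into one giant event. Each potential is sourced from the contributing
   channel with the greatest peak-trough amplitude in the merged span;
   spans are clipped at inter-seed midpoints so they never overlap.
6. **Noise bands and inclusion.** A potential's local noise band is
   mean(positive samples) − mean(negative samples) on its source channel
   over the one-second windows flanking its span, truncated at recording
   edges, with samples inside any other potential's span removed (an empty
   sign class contributes 0; a completely empty window leaves the noise
   band undefined and the potential excluded). The amplitude inclusion
   threshold is 8× the noise band; a potential is included when its
   peak-trough amplitude reaches it. The recording-level noise readout is
   the *median* of all noise bands — robust to the occasional large
   outlier. For Gaussian noise of SD σ the noise band converges to
   2σ·√(2/π) (half-normal means), which the tests verify by Monte Carlo.
7. **Noisy-block exclusion.** The recording is tiled into 5 s blocks. A
   block is excluded when (a) the inclusion threshold exceeded the 100 μV
   exclusion threshold for more than half of its potentials, or (b) any
   single inclusion threshold exceeded double it. Excluded blocks forfeit
   their duration and their potentials. The final partial block is judged
   by the same rules but only its actual duration is subtracted.
8. **Voluntary-activity identification.** A *voluntary train* is ≥ 4
   potentials whose consecutive inter-spike intervals are all strictly
   below 250 ms (4 Hz is the lowest recruitment rate; sub-50 ms multiplets
   stay analysable). Blocks of a configurable duration are flagged when
   they contain a train, evaluated strictly within the block — that
   within-block rule is what makes 1 s blocks specific and 10 s blocks
   sensitive. Strategies: `0` disabled; `1A` exclude every flagged 10 s
   block; `1B` as 1A but a classifier may return false positives to the
   analysable pool; `2` exclude every flagged 1 s block. Voluntary
   exclusion runs *after* noisy-block exclusion (so artefact spikes cannot
   form spurious trains) and is credited only for time not already removed
   as noisy, making the time accounting exact:
   analysed + noise-excluded + voluntary-excluded = duration.
9. **Classifier (strategy 1B).** Eight per-block interval features:
   median, mean, mode, SD, IQR of all consecutive intervals (ms), the
   per-minute potential frequency, and — over intervals inside the
   84–250 ms band (4–12 Hz voluntary firing) — Pearson kurtosis and the
   in-band proportion. The model is a bagged ensemble of 30 decision trees
   (no dimensionality reduction), evaluated by stratified 5-fold
   cross-validation reporting accuracy, PPV and NPV; a flagged block is
   confirmed voluntary at probability ≥ 0.5. Everything is seeded.
10. **Readouts.** Inter-potential interval histogram (10 ms bins over
    0–400 ms, intervals straddling an excluded epoch dropped), a potential
    timeline with excluded epochs shaded, the one-row recording summary,
    and an advisory strategy recommendation.

## Numerical conventions

* Interval **mode**: 10 ms histogram bins *centred* on multiples of 10 ms,
  centre of the maximal bin, ties toward the smaller interval (so constant
  100 ms intervals give exactly 100).
* **SD** of intervals is the sample SD (ddof = 1); IQR uses
  linear-interpolation percentiles.
* **Kurtosis** is Pearson (non-excess, biased); with fewer than four
  in-band intervals, or (near-)identical ones, the Gaussian reference
  value 3 is recorded.
* Fewer than two potentials in a block leave the features undefined; such
  a block is treated as non-voluntary without classification.
* Noisy-block rule ties: when both exclusion rules fire, the majority rule
  is reported.
* Degenerate inputs: constant channels screen no events (with a warning);
  zero analysable time leaves the frequency missing rather than infinite.

## Strategy recommendation heuristics

The advisory readout suggests strategy `0` when no interval-histogram bin
in 100–200 ms exceeds k = 3 times the median bin count over 250–400 ms.
Otherwise it suggests `1A`, escalating by the fraction of flagged 10 s
blocks (> 0.5 → `2`, > 0.8 → `1B`). The escalation thresholds are
heuristics of this package, not published quantities; the CLI always
requires an explicit strategy.

## Synthetic-data generator

The generator emulates the study conditions with full ground truth:

* **Fasciculations**: homogeneous Poisson process at a configurable rate
  (default 40/min, a typical observed median) thinned by a 10 ms absolute
  refractory period; each event is its own unit with its own epicentre.
* **Voluntary units**: regular firing at 4–12 Hz (default 7 Hz) inside
  declared epochs; ISIs are `rate⁻¹(1 + 0.12·N(0,1))`, clipped to
  [refractory, 249 ms] so every generated train satisfies the detector's
  own train definition (generator–detector self-consistency is a tested
  invariant).
* **Multiplets**: a partner spike of identical morphology 30 ms
  (configurable, < 50 ms) after its parent.
* **Waveforms**: a triphasic, sqrt-Hanning-windowed sine template of
  ~15 ms, peak-normalised; per-spike amplitude is 300 μV with log-normal
  scatter (σ = 0.3). Channel weights decay exponentially with grid
  distance from the epicentre (e-folding 1.7 electrode pitches), so every
  interior epicentre reaches ≥ 10 channels above quarter amplitude — the
  premise of multi-channel motor-unit identification. Epicentres are drawn
  uniformly over the grid interior (one-pitch margin).
* **Noise**: additive Gaussian noise (default SD 3 μV, matching observed
  noise-band medians of a few μV), common-phase 50 Hz line interference,
  slow (0.2 Hz) per-channel sinusoidal drift, and optional dead channels.

What it does *not* model: volume conduction and electrode impedance
physics, motor-unit recruitment/force relationships, waveform variability
within a unit, non-stationary noise, or movement artefacts. Passing tests
therefore demonstrate the pipeline's logic and statistical behaviour under
the stated model, not clinical performance on real recordings.

Fixture presets (`relaxed`, `partially_relaxed`, `voluntary`, `noisy`,
`mixed`) mirror how resting recordings present in practice. Desk-test
fixtures are 60 s × 64 channels (≈ 7.9 M samples, ~1 s to generate and
~1 s to process), which keeps the full suite and the acceptance script in
the minutes range; durations are parameters, so 30-minute simulations are
one flag away.

## Known limitations

* EDF is read (via MNE) but not written; the lossless on-disk format is
  the documented JSON-header + TSV matrix.
* The classifier for strategy 1B must be trained on labelled blocks; a
  synthetic labelled-block generator is provided, and any table with the
  eight features can substitute.
* Channel QC assumes a population of ≥ 8 comparable channels; tiny grids
  skip it.
* The screen's prominence condition assumes spikes are biphasic/triphasic;
  a strictly monophasic event would be ignored by design.
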