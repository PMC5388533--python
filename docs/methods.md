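# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind each flysip module, in the order data flows through the
package.

## FLIC contact detection

**Signal model.** A FLIC well produces a sampled voltage-like signal
(arbitrary units) that is near a slowly drifting baseline while the fly is
away from the food and elevated while it is in contact. Detection treats
contacts as approximately rectangular excursions above the baseline.

**Baseline.** A running median over `baseline_window_s` (default 120 s),
edge-padded by reflection. The median tracks drift on the minutes scale
while being essentially insensitive to contacts, which occupy a small
fraction of any window at realistic contact rates (~2/min × ~2 s ≈ 7% duty
cycle). The window must be long relative to the longest bout and short
relative to the drift period; 120 s satisfies both by an order of magnitude
at the defaults.

**Threshold.** Either absolute (`threshold`, a.u. above baseline) or
adaptive (`threshold_mads`, default 6, times the scaled median absolute
deviation 1.4826·MAD of the baseline-subtracted residual — a robust noise-sd
estimate that event samples barely inflate). At the default synthetic
signal-to-noise (event amplitude 100, noise sd 5) the adaptive threshold
sits near 30 a.u., far from both the noise and the events, so recall and
false-positive rate are insensitive to its exact value.

**Segmentation.** Maximal runs of samples strictly above threshold become
candidate events. Each sample is taken to represent the interval
[t, t + 1/fs), so an event ends one sample interval after its last
supra-threshold sample; this makes a k-sample run k/fs seconds long, the
unbiased duration accounting for a square pulse sampled at rate fs. Runs
separated by gaps shorter than `merge_gap_s` (default 0.2 s — one sample at
5 Hz) are merged; events shorter than `min_event_duration_s` (default
0.4 s) are dropped. The merge gap is deliberately the minimum that bridges a
single-sample dropout: a wider gap (e.g. 1 s) would fuse genuinely distinct
bouts, which at a Poisson contact rate of 2/min occur within 1 s of each
other about 3% of the time, and every such fusion costs a miss under
one-to-one validation matching.

**Validation.** Greedy one-to-one matching in time order: a detection and a
truth interval match if they overlap or their boundary gap is ≤ `tol`
(default 0.5 s); on a mismatch the interval ending earlier is advanced
(deterministic, earliest-first). Detection rate = matched/true;
false-positive rate = unmatched detections/detections, defined as 0 when
nothing was detected (avoids 0/0 and is conservative). An empty truth set
has detection rate 1 by convention.

**Residual error sources on the synthetic benchmark.** Two effects
dominate the ~0.5–1.5% of true contacts the detector cannot recover: truth
pairs separated by less than the sampling resolution appear as one run (a
resolution limit, not a parameter choice), and bouts from the short lognormal
tail (< 0.4 s) fall under the minimum-duration rule. Both are properties of
the stated contact process, not of noise; false positives are effectively
absent because a 6-robust-sd threshold with a two-sample minimum duration
requires an astronomically unlikely noise excursion.

## Calcium-imaging ΔF/F

F₀ is the arithmetic mean of the 10 non-excluded frames nearest before
stimulus onset; when flagged frames fall in that window it slides earlier
until 10 usable frames are collected (interpolation would fabricate data the
microscope did not record). Bins of `bin_width_s` (default 30 s) are aligned
to the stimulus application time, not to response onset, and only complete
bins are reported; `dff` is (max non-excluded intensity − F₀)/F₀ per bin.
A bin that keeps fewer than 2/3 of its nominal frames is flagged
`low_coverage` — refocusing episodes are 5–10 s, so losing more than 10 s of
a 30-s bin is anomalous — and a bin with no usable frame reports NaN, never
zero (zero would understate a response). NaN bins are dropped from group
time-course means and from n.

Note one statistical property of the per-bin **maximum**: on a null
(water-like) trace the bin maximum of pure noise sits ~2 noise-sd above
zero, so null ΔF/F time courses hover slightly above zero rather than at it.
This bias is shared by any max-per-bin readout and is small relative to real
response amplitudes (~1.0).

The simulator's response kernel g(u) = (1 − e^(−u/τr))·e^(−u/τd),
normalized to unit maximum, peaks at u* = τr·ln(1 + τd/τr); the default
kinetics (τr = 13 s, τd = 120 s) put u* ≈ 30.2 s, matching the observed
~30 s rise to peak, and place the strongest bin at 30–59 s post-stimulus.

## Dye calibration and ingested volume

The standard line is a least-squares fit of mean OD₆₃₀ against dilution
level constrained through the origin, because the downstream conversion
uses the slope alone; the RMS residual is kept on the curve object so the
through-origin choice can be audited. Levels are expressed in
μl-equivalents of the 0.4 μg/μl erioglaucine reference (1.0, 0.5, …,
1/512), which reconciles the slope's OD/μl unit with a series described as
concentration dilutions. The dataclass enforces the two-fold structure;
replicate counts ≥ 1 are accepted (the bench protocol reads ≥ 3 per level
and ≥ 4 per fly extract).

Volume = (mean OD − background)/slope, where background is the mean OD of
extracts from flies fed undyed food. Readings below background clamp to
zero with a `below_background` flag rather than erroring: negative volumes
are unphysical, but the flag preserves auditability.

Ingestion rate is the OLS slope of volume (nl) on feeding time (s), with
intercept — matching how regression lines through cohort scatter are drawn —
and the squared Pearson correlation. A 20-fly cohort with between-fly rate
CV 0.21 carries ~13% sampling error on a single fitted slope (the error
term (rᵢ − r̄)tᵢ scales with t); parameter-recovery checks therefore use the
median slope over many seeded cohorts, which estimates the recovered rate
itself rather than one cohort's draw.

## Pumping-assay rules

Inclusion is checked in chronological order: water pre-test strictly longer
than 10 s discards the fly ("longer than 10 s" is read as strict
inequality, so exactly 10 s is kept); a fly initiating no bout within its
first four presentations is a non-responder. Excluded sessions never enter
any aggregate. Summaries are total bout time, total swallows, and their
ratio (the pumping rate); the pooled swallow-versus-time R² is the squared
Pearson correlation over included flies. The 2-s-offer/3-s-rest
presentation cadence is metadata only — no derived quantity uses it.

## Synthetic-data conditions

The generators' defaults are the study conditions the analyses assume, not
tuning knobs:

- **FLIC** (`FlicSimConfig`): 900 s at 5 Hz (the instrument class's typical
  rate; all downstream code infers the rate from the time axis), baseline
  0 a.u., square contacts of amplitude 100, Gaussian noise sd 5, sinusoidal
  drift bounded by 10 a.u. (two random slow periods, 240–600 s), Poisson
  contacts at 2/min with lognormal bout durations (median 2 s, σ = 0.5).
  Overlapping simulated contacts are merged into one truth interval — a fly
  cannot be in two contacts at once. Mutant-like wells use a 3× bout-duration
  median at the same contact rate.
- **Calcium** (`CaSimConfig`): 1 frame/s; 30 s of baseline followed by
  300 s post-stimulus (ten complete 30-s bins); f₀ = 100 a.u., peak ΔF/F
  amplitude 1.0 (water-like controls: 0), noise sd 2 (2% of f₀); optional
  refocus gaps flagged excluded.
- **Pumping/dye** (`PumpSimConfig`): 140 flies by default (the pooled
  correlation cohort size; volume-regression cohorts override to 20),
  feeding times uniform on 5–60 s, pumping rate mean 2.0 swallows/s with
  CV 0.13 (unreported upstream; chosen so the pooled swallow-versus-time R²
  matches the observed ≈ 0.91 via the variance decomposition
  R² = r̄²Var(t)/(r̄²Var(t) + E[t²]σr²)), ingestion rates 8.0 nl/s (control)
  and 7.8 nl/s (mutant) with CV 0.21 (which reproduces the observed
  volume-versus-time R² ≈ 0.76), dye absorptivity 0.14 OD/μl, background
  OD 0.05, OD read noise sd 0.005.
- **Sessions** (`gen_session_cohort`): up-to-four Bernoulli initiation
  attempts (non-responder fraction has closed form (1 − p)⁴), lognormal
  water pre-tests placing ~5% of flies over the 10-s limit at the defaults,
  one to three bouts per responder.

**What the generators do not emulate**: real FLIC noise is not described
distributionally upstream, so Gaussian noise plus sinusoidal drift is an
idealization — no mains interference, leg-touch vs. feeding amplitude
classes, or grooming artifacts; fluorescence has no bleaching, motion, or
z-drift beyond the binary excluded flag; cohorts have no satiety dynamics or
day effects. Passing tests therefore demonstrate algorithmic correctness
and parameter recovery under the stated statistical structure, not
instrument-grade robustness on real recordings.

## Validation problem sizes and expectations

The end-to-end checks use 50 wells (15 min, 5 Hz) for detector validation,
201 seeded 20-fly cohorts for each ingestion-rate recovery, 50 seeded
140-fly cohorts for the pooled correlation expectation, and 30 wells per
genotype for the contact contrast. Two realized-versus-nominal gaps are
expected and documented rather than hidden:

- With 3× bout durations at an equal contact rate, interval overlap makes
  the realized total-contact-time ratio fall slightly below 3 (Boolean
  coverage model: T·(1 − e^(−λE[d])) per genotype gives ≈ 2.8 at these
  settings) and the mutant contact count ~15% below control.
- The pooled R² of a single 140-fly cohort scatters with sd ≈ 0.013 around
  its expectation ≈ 0.919, so the ≥ 0.91 bound is checked on the
  expectation (mean over seeded cohorts), not on one draw.

## Degenerate inputs and tie-breaks

Empty traces detect no events (not an error); an all-zero residual yields a
zero adaptive threshold and hence no detections (strict inequality). Greedy
matching advances the earlier-ending interval on a mismatch, making reports
deterministic. All-zero dilution standards, zero-variance regressions, and
correlations on constant inputs raise `DegenerateFitError`; calling
`summarize_session` on an excluded session raises `UsageError`. Config
dataclasses validate on construction and name the offending field.
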