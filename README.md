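# flysip

Quantitative analysis of *Drosophila* feeding behavior, built around four
measurement pipelines that recur in studies of feeding regulation by
pharyngeal taste neurons:

- **FLIC contact-event detection** (`flysip.flic`) — the Fly Liquid-Food
  Interaction Counter records a capacitive signal that rises while a fly
  touches liquid food. The detector removes slow baseline drift with a
  running median, segments samples above a threshold (absolute, or a
  multiple of the residual's scaled MAD) into maximal supra-threshold runs,
  merges sub-sample dropouts and drops sub-duration blips, then summarizes
  per-fly contact counts, total contact time, and time per contact.
  Detections can be scored against ground-truth intervals by greedy
  one-to-one matching (detection rate, false-positive rate).
- **Binned ΔF/F calcium responses** (`flysip.calcium`) — per-frame ROI
  fluorescence of GCaMP-expressing pharyngeal neurons (nominally 1 frame/s)
  is converted to a per-30-s-bin maximum ΔF/F = (max F − F₀)/F₀, where F₀
  is the mean of the 10 usable frames immediately before stimulus delivery;
  frames flagged during refocusing are excluded.
- **Dye-based ingested volumes** (`flysip.volume`) — a through-origin
  standard line (OD₆₃₀ per μl-equivalent of the erioglaucine reference,
  from a 10-level two-fold dilution series) converts background-subtracted
  extract absorbance into ingested volume; OLS of volume on feeding time
  yields the ingestion rate in nl/s.
- **Pharyngeal pumping assay bookkeeping** (`flysip.pumping`) — applies the
  assay's inclusion rules (water pre-test > 10 s discards the fly; no bout
  initiated within four presentations marks a non-responder), computes total
  feeding time, swallow count and pumping rate per fly, and pools the
  swallow-versus-time correlation.

A synthetic-data module (`flysip.simulate`) generates all four input kinds
with known ground truth — Poisson contact bouts with lognormal durations,
double-exponential fluorescence responses peaking ~30 s after stimulus
onset, and cohorts with constant per-fly pumping and ingestion rates — so
every pipeline can be validated end to end.

## Worked example

Simulate one 15-minute FLIC well, detect contacts, and score them against
the generator's ground truth:

```python
from flysip import detect_events, summarize, validate
from flysip.simulate import FlicSimConfig, gen_flic_trace

cfg = FlicSimConfig(seed=42)                       # 15 min at 5 Hz, ~2 contacts/min
trace, truth = gen_flic_trace(cfg)
events = detect_events(trace)                      # default detector settings
report = validate(events, truth, tol=0.5)
stats = summarize(events, window=(0, 900), well_id=trace.well_id)

print(f"detection rate     : {report.detection_rate:.3f}")
print(f"false-positive rate: {report.false_positive_rate:.3f}")
print(f"total contact time : {stats.total_contact_time_s:.1f} s")
print(f"mean contact bout  : {stats.mean_contact_duration_s:.2f} s")
```

```
detection rate     : 1.000
false-positive rate: 0.000
total contact time : 69.4 s
mean contact bout  : 2.10 s
```

All 33 simulated contacts in this well are recovered with no false
positives; the fly spent 69.4 s in contact with the food, 2.1 s per bout on
average. Recovering an ingestion rate from a simulated 20-fly dye cohort is
equally direct:

```python
from flysip.simulate import PumpSimConfig, gen_pumping_cohort
from flysip.volume import fit_rate

df = gen_pumping_cohort(PumpSimConfig(n_flies=20, seed=0))
fit = fit_rate(df["feeding_time_s"], df["true_volume_nl"])
print(f"ingestion rate: {fit.slope_nl_per_s:.2f} nl/s  (R^2 = {fit.r_squared:.2f}, n = {fit.n})")
```

```
ingestion rate: 8.62 nl/s  (R^2 = 0.86, n = 20)
```

The fitted slope scatters around the generator's 8 nl/s control rate with
the between-fly spread a 20-fly cohort implies.

## Command line

One executable with simulation and analysis subcommands:

```bash
flysip simulate flic --seed 1 --n-traces 12 --out run/
flysip flic-detect --in run/trace.csv --out run/events.csv
flysip flic-validate --events run/events.csv --truth run/truth.csv --tol 0.5
flysip simulate ca --seed 1 --out ca/ && flysip dff --in ca/roi.csv --onset 30 --out ca/dff.csv
flysip pump-summary --in sessions.csv --out summary.csv
```

Every simulation writes a `manifest.json` recording parameters, seed, and
package version; the same seed reproduces byte-identical CSVs.

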