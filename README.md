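# endoqc

A software test bench for optical quality assurance of rigid endoscopes.
It reproduces, entirely in software, the workflow of an opto-electronic QA
bench used at a sterilization department: generate on-screen test patterns,
capture them through a (here: simulated) endoscope, compute calibrated
fibre-transmission units and a histogram-quantile contrast statistic, store
every measurement in a database, and drive database-relative
acceptance/rejection decisions plus longitudinal trend tracking.

## What's inside

| module | purpose |
| --- | --- |
| `endoqc.patterns` | 7 binary line patterns of increasing spatial frequency + circular ROI pattern |
| `endoqc.optics` | virtual endoscope: field mask, blur, veiling glare, vignetting, dust, noise; photocell simulation; aging, repairs, fleet histories |
| `endoqc.metrics` | ROI location, 25%–75% cumulative-histogram contrast, transmission units |
| `endoqc.registry` | SQLite measurement store with CSV import/export and best-of-type lookup |
| `endoqc.qa` | acceptance (≥40% of best-of-type, both metrics), rejection (<20%, either metric), >5% change significance |
| `endoqc.trends` | reference stability (band fractions, OLS drift test), per-endoscope trends, before/after-repair classification |
| `endoqc.cli` | the `endoqc` command |

## CLI

```bash
# emit the default test-pattern suite (PNG + JSON sidecars)
endoqc patterns --size 512 --out patterns/

# run the fleet simulator from a config file
endoqc simulate --config cfg.json --seed 3 --out sim/

# measure one endoscope from captured images + a photocell reading
endoqc measure --captures captures/ --reading reading.json \
    --serial SN123 --type-id T42 --timestamp 2021-07-07T10:00 \
    --context NEW --out record.json

# database operations
endoqc db add --db fleet.db --record record.json
endoqc db best --db fleet.db --type-id T42 --metric TRANSMISSION
endoqc db export --db fleet.db --csv records.csv

# decisions and reports
endoqc decide --record record.json --db fleet.db --mode acceptance
endoqc report stability --db fleet.db --serial REF-0001 --metric TRANSMISSION
endoqc report trend --db fleet.db --serial SN123 --metric CONTRAST --plot t.png

# full synthetic measurement-period study (deterministic per seed)
endoqc demo --seed 7 --out demo/
```

`demo` simulates a reference endoscope (measured every session, never
degrading) plus a fleet of clinical endoscopes that age between sessions
and are repaired when a metric drops below the rejection level; it stores
every record, exports CSVs, and writes stability/trend/repair reports.
Re-running with the same seed produces byte-identical outputs.

## Conventions worth knowing

- Contrast quantiles take the smallest grey level whose ascending
  cumulative count reaches ⌈q·N⌉ — no interpolation — so the statistic
  equals a difference of order statistics of the ROI pixels.
- Acceptance is inclusive at the boundary ("at least"); rejection is
  strictly below; change significance is strictly above 5%.
- Both metrics must pass acceptance independently; either metric alone can
  trigger rejection. Moisture is recorded and flagged but never rejects on
  its own.
- Best-of-type is the running per-metric maximum over all stored records of
  a type.
- Simulator degradation rates are illustrative, not clinical estimates.
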