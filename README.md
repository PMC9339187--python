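# saltgill

Analysis toolkit for multiplexed isobaric-label (iTRAQ/TMT-style) proteomics
of fish gill tissue across a **bidirectional salinity gradient**: two
hyposaline groups (0 and 10 ‰), a 25 ‰ control and two hypersaline groups
(35 and 50 ‰), each quantified as reporter channels of the same runs. It is
aimed at comparative physiologists who have per-protein channel intensities
(or ratios) and want the full downstream chain — differential-expression
calling, salinity-response classification, term enrichment, and the
companion cultured-cell ion-flux computation — as tested, scriptable code.

Because raw study data of this kind are rarely public, the package ships a
first-class synthetic-data generator that emulates the design with planted
ground truth, so every stage can be validated for recovery and calibration.

## Method

**DEP calling.** For protein *i*, condition *c*, run *r*, the treatment /
control channel ratio is median-normalised per (run, condition):
*R*ᵢ꜀ᵣ = (xᵢ꜀ᵣ/xᵢ,ctrl,ᵣ) / medianᵢ(xᵢ꜀ᵣ/xᵢ,ctrl,ᵣ). After removing proteins
with < 2 unique peptides, each protein × condition is tested with a
one-sample two-sided *t*-test of log₂ *R* across runs against 0; the
reported fold change is the geometric mean across runs. A protein is called
**up** when *R* > 1.20 with *p* < α (= 0.05) and **down** when *R* < 0.83
(the conventional rounded reciprocal; both cutoffs are independent
settings). The multiple-testing correction (Bonferroni default, BH or none)
and its family (per condition, global, or per protein) are configurable.

**Response classification.** Each protein's four calls (0, 10, 35, 50 ‰)
map to one of seven disjoint classes: *osmoregulatory* (monotone with
salinity, positive or negative), *non-directional* (same direction under
both stresses, up or down), *hypo-* or *hyper-exclusive* (one arm responds
consistently, the other is entirely ns), else *unclassified*. A strictness
switch controls whether a responding arm needs both comparisons significant
(`all`, default) or at least one with none opposing (`any`).

**Enrichment.** Over-representation of a protein set against a background
via the upper-tail hypergeometric probability P(X ≥ k) with BH adjustment,
on user-supplied GMT term maps.

**Ion flux.** Ion-chromatography readings of diluted culture media convert
to net movement per 10⁶ cells:
`(measured × dilution − baseline) × volume / (cells/10⁶)`,
positive = efflux, negative = influx.

## Worked example

```python
from saltgill import load_config, run_pipeline

config = load_config("examples/run_config.json")   # 400 proteins, 3 runs
manifest = run_pipeline(config, "demo_out")
```

With the bundled demo configuration (seed 42, log₂ noise SD 0.1, raw-p
thresholds) the run prints per-stage timings and writes `demo_out/`:

```
dep_summary.json    per_condition: 0‰ 15 up / 2 down, 10‰ 15/2,
                    35‰ 11/4, 50‰ 11/4
class_counts.json   osmoregulatory 4, non_directional 3,
                    hypo_exclusive 10, hyper_exclusive 8, unclassified 226
```

meaning: of the 251 proteins surviving the two-peptide filter, 4 track
salinity monotonically, 3 respond in the same direction under both
stresses, 10 respond only to hyposaline and 8 only to hypersaline exposure
— close to the generator's planted class mix. `manifest.json` records a
deterministic hash (`7b3a14692ef651fe…` for this config); rerunning the
same config and seed reproduces every file byte-identically.

The same stages are available as a CLI:

```sh
saltgill simulate  --out-dir sim --seed 3
saltgill call-deps --quant sim/quant.tsv --control 25 --correction none --out deps
saltgill classify  --stats deps/comparison_stats.tsv --out classes
saltgill pipeline  --config examples/run_config.json --out-dir out
```

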