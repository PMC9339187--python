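# Methods

## Design being modelled

The package targets a five-group environmental-salinity experiment on gill
tissue: hyposaline stress at 0 and 10 ‰, a 25 ‰ control, hypersaline stress
at 35 and 50 ‰, with each group occupying one reporter channel of a
multiplexed isobaric-label run and three runs serving as technological
repeats. All inference is on treatment/control channel ratios within runs;
between-run scale differences cancel in the ratio and the remaining
mix-ratio bias is removed by median normalisation.

## Synthetic-data generator

The generator's channel model is

    x[i, c, r] = b_i * 2^(e[class(i), c] + eps[i, c, r]),
    eps ~ Normal(0, sigma),  e[., control] = 0,

with log2-scale noise `sigma` independent across proteins, conditions
(including the control channel) and runs. A null protein's log2 ratio
therefore has SD `sigma * sqrt(2)` — the closed form the marginal tests
check against.

Choices made where the design was open:

- **Baselines** `b_i` are log-uniform over three decades (1e4–1e7).
  This gives a realistic dynamic range without modelling spectra; ratios
  are scale-free, so the range affects nothing downstream.
- **Unique-peptide counts** follow a shifted geometric distribution
  (support ≥ 1, default p = 0.35), so the two-peptide filter removes a
  tunable ~35 % of proteins. Only the filter itself, not the count
  distribution, matters downstream.
- **Defaults** are the design scale: 1,600 proteins × 3 runs,
  `sigma = 0.1` (≈ 7 % channel CV), planted effects ±1 log2 unit, and a
  class mix proportioned like the selected-DEP counts of the motivating
  design (~0.9 % osmoregulatory + mirror, ~1.1 % non-directional,
  3.25 % hypo-exclusive, 2.5 % hyper-exclusive, remainder null).
- **No missing values, reporter interference or ratio compression** are
  simulated; the generator's noise is i.i.d. Gaussian in log space.
  Passing recovery tests therefore demonstrate correctness of the chain
  under a well-behaved error model, not robustness to the correlated,
  intensity-dependent artefacts of real reporter-ion data.
- Ground truth is written beside the table so recovery tests never
  re-derive it.

The GMT fixture generator plants enrichment by drawing a term's overlap
with a chosen response class from Fisher's noncentral hypergeometric
distribution at a configurable odds ratio (uniform within strata);
`odds_ratio = inf` draws the term wholly from the class, and 0 enriched
terms gives an exact null. The ion-chromatography generator inverts the
flux formula around per-(ion, osmolality) mean fluxes shaped on the
cultured-cell experiment (hypotonic efflux, hypertonic influx; the
unreported K⁺ isotonic mean defaults to 0), with medium volume 8 mL,
10⁶ cells and L-15-like baseline concentrations as explicit configuration.

## DEP caller

- The *t*-test is one-sample on per-run log2 normalised ratios against 0.
  With pooled-sample channels there is one ratio per run, so a paired or
  two-sample construction has no data to act on; the one-sample ratio test
  is the only design consistent with the layout.
- **Degenerate inputs** follow fixed rules: < 2 runs → p = 1 and `ns`
  (logged); zero across-run variance → p = 0 if the mean log2 ratio is
  non-zero else 1 (logged). The zero-variance rule makes the noise-free
  limit exactly recoverable.
- **Correction family** defaults to Bonferroni within each condition's
  protein family (each condition is a separately reported comparison);
  `global` and `per_protein` (across the four conditions only) are
  available, as is `correction="none"`.
- With three runs the *t* statistic has 2 degrees of freedom, so the
  smallest achievable raw p for even a huge, consistent effect is ~7e-3;
  a Bonferroni factor of ~1,600 then makes any adjusted call impossible.
  Recovery-oriented analyses (and the acceptance script) therefore read
  the significance rule as raw p < 0.05 combined with the fold cutoffs —
  the thresholding that volcano-plot screening conventions apply — while
  the stricter families remain available for confirmatory use.
- Fold changes aggregate across runs as the geometric mean (arithmetic
  mean of log2 ratios), the natural aggregator for ratios.
- Proteins quantified in ≥ 2 but not all runs are retained for calling.
- Reported percentages (replicate overlap) round half-up to one decimal.
- Up (1.20) and down (0.83) cutoffs are independent config entries; 0.83
  is the conventional rounded reciprocal of 1.20 and the printed asymmetry
  is preserved exactly, with strict inequalities (a ratio of exactly 1.20
  or 1.0 is `ns`).

## Response classifier

"Consistently correlated with salinity" is operationalised as significance
with the stated direction pattern in **all four** comparisons
(`strictness="all"`), because the canonical osmoregulatory examples
(NKCC1-like patterns) change significantly in every comparison. The `any`
relaxation (≥ 1 significant, none opposing, per arm) is provided for
screening. Exclusive classes additionally require direction agreement
within the responding arm — a mixed-direction arm is not interpretable as
a single response — and a fully `ns` opposite arm. The seven classes are
mutually exclusive under both settings (verified by exhaustive enumeration
of all 3⁴ call vectors against an independent truth-table oracle).
Direction-pooled totals (osmoregulatory, non-directional) are emitted
alongside the directed counts.

## Enrichment

Self-contained upper-tail hypergeometric test on supplied GMT maps; no GO
DAG propagation or pathway-database access. The recommended background is
the quantitated-protein universe, not all identified proteins — enrichment
against an inflated background overstates significance. BH adjustment is
the default; figure-style filtering (raw p < 0.05, top 10) is available in
`top_terms`. p-values are validated against exact combinatorial enumeration
for all universes N ≤ 25. Being discrete, the hypergeometric p is
super-uniform (conservative) under the null, which is what the calibration
tests assert.

## Ion flux

`net_flux = (measured_conc × dilution_factor − baseline_conc) ×
medium_volume / (cell_count / 1e6)` is the only dimensionally consistent
construction producing mass per 10⁶ cells from diluted-medium readings;
baseline concentration, medium volume and cell count are required inputs
rather than assumed constants. "1:100 dilution" is read as the diluted
sample sitting at 1/100 of the original concentration (measurement × 100).
Positive flux = efflux. A configurable dead band (default 0) widens the
"none" direction for instrument noise. SEM is sample SD/√n, reported as 0
with a warning when n = 1.

## Pipeline and reproducibility

A single JSON config drives all stages; thresholds are validated up front
(up > 1, 0 < down < 1, 0 ≤ α ≤ 1). The manifest hashes the canonical
config and every output file; timings are logged but excluded from the
hash, so identical config + seed ⇒ identical manifest hash and
byte-identical outputs. An empty DEP set (e.g. α = 0) cascades without
error: all proteins unclassified, enrichment skipped with a notice.

## Problem sizes in the shipped checks

The test suite and acceptance script run the generator at 100–2,000
proteins and the study-scale 1,600 × 3 design, 3-seed batches for noisy
recovery, 400-draw Monte-Carlo loops for null calibration and 1,000 draws
for the noncentral-overlap oracle; the whole suite completes in well under
a minute on one core, and the acceptance script in a few seconds.

## Known limitations

- No peptide-to-protein inference, identification-level FDR, or missing
  values: the quantitation table is taken as given.
- The classifier is specific to the 2 + 2 condition design around one
  control; other gradients need a generalised truth table.
- Synthetic validation bounds what can be claimed about real data (see the
  generator's non-goals above); the printed-value checks in the test suite
  cover the arithmetic identities and worked patterns that are
  reproducible without the original raw data.
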