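# hma — heterotypic multicellular-aggregate morphometry

Glioblastoma cells from different patients differ in how strongly they adhere
to their own kind.  When a patient-derived line is co-cultured with two
reference lines (U251, strongly self-adhesive; U87, weakly adhesive) in a
non-adhesive 500-μm microwell, the cells self-assemble into a single
aggregate whose radial layering reports intercellular affinity: strongly
adhesive populations pack into the core, weakly adhesive ones are pushed to
the periphery.  That spatial readout correlates with temozolomide (TMZ)
resistance and, through it, with patient outcome.

`hma` implements this assessment as a tested pipeline for researchers
working with microwell aggregate images and the matching phenotype/survival
tables:

* **zonation** — partition a well into *n* concentric zones of equal radial
  width (Zone I innermost … Zone V outermost) and measure, per fluorescence
  channel, the thresholded pixel area and occupancy fraction per zone
  ("circular sector analysis").
* **scoring** — summarise a zone profile by the area-weighted mean zone
  index, `score = Σₖ k·fₖ` (1 = fully internal, n = fully external);
  classify a test population against the U251/U87 references; rank
  populations 1..n and split them into internal/external subgroups at the
  median rank.
* **phenotypes** — TMZ resistance (normalised log-dose AUC of the
  dose–viability curve), proliferation (slope of ln OD vs time) and invasion
  (relative invaded-area change 0→72 h), ranked with the same semantics and
  compared to the spatial ranking by Spearman ρ and subgroup agreement.
* **survival** — Kaplan–Meier product-limit curves and the two-group
  log-rank test, implemented from their defining formulas.
* **synthetic** — seeded generators for well images (disk-shaped cells with
  per-zone or core–shell radial placement), coupled phenotype tables and
  two-group survival records, so the entire pipeline runs and is tested
  without any external data.

## Worked example

The repository ships a demo configuration with the two reference lines and
six patient-like populations spanning internal → external placements:

```
hma run --config examples/demo.yaml --out-dir demo_out --no-timestamp
```

prints

```
spearman_rho=1.0000 group_agreement=1.0000 logrank_p=2.13e-06
```

and writes `demo_out/summary.json` containing, among others,

```
"spatial_scores": {
  "U251": 1.43, "TS-A": 1.52, "TS-B": 2.44, "U87": 2.55,
  "TS-C": 3.14, "TS-D": 3.61, "TS-E": 4.34, "TS-F": 4.69
}
```

Reading: the measured radial score orders the populations from internal
(U251 ≈ 1.4, signal in Zones I–II) to external (TS-F ≈ 4.7, signal at the
rim).  With the demo's noiseless resistant-when-external coupling, the TMZ
resistance ranking reproduces the spatial ranking exactly (ρ = 1, subgroup
agreement 100%), and the synthetic internal-vs-external cohorts separate in
survival (log-rank χ² = 22.5, p ≈ 2×10⁻⁶).  Intermediate files
(`zone_profiles.csv`, `rank_table.csv`, `phenotype_metrics.csv`,
`km_curves.csv`, …) are CSVs with provenance headers; every stage is also
available as its own subcommand (`hma simulate | zonate | score | phenotype
| correlate | survive`).

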