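# Methods

## The measurement

A microwell aggregate image is a multichannel, optionally z-stacked
fluorescence stack in which each labeled cell population occupies one
channel.  The well (default diameter 500 μm) is partitioned into `n_zones`
(default 5) concentric annuli of **equal radial width** R/n; Zone 1 is
innermost.  Zonation is cylindrical: the radius is the xy distance to the
well center, every z-slice is binned with the same mask, and per-slice
above-threshold pixel counts are summed over z and converted to μm².
Per-channel occupancy fractions are the zone areas normalised over zones
1..n; thresholded signal outside the outermost zone is excluded from the
fractions but reported, with a warning above 5% of channel signal (a
mis-centered well is the usual cause).

Choices a user should know:

* **Equal width, not equal area.**  Equal-width rings are what concentric-
  zone schematics conventionally show; equal-area zones would change every
  stated occupancy.  The zone count is configurable.
* **Well center.**  By default the intensity-weighted centroid of the
  summed-channel, summed-z image (exact for radially symmetric aggregates);
  an explicit center can be supplied in `WellGeometry`.  An all-zero image
  falls back to the geometric image center and flags it.
* **Threshold.**  Default is Otsu's method computed per channel over the
  in-well region of the max-intensity z-projection, then applied to every
  slice; `fixed:<v>` gives a reproducible alternative.  A channel with no
  above-threshold pixel is reported as *missing* (never as a zero profile).
* **Binning convention.**  Pixel-center coordinates, 0-based indices scaled
  to μm; half-open bins `(k−1)·R/n ≤ r < k·R/n` with the outermost bin
  closed at r = R; label 0 outside the well.  This is a deterministic,
  complete partition, and the vectorised implementation is tested for exact
  integer agreement with a per-pixel loop oracle.

## Scores, classification, ranking

The scalar summary of a profile is the area-weighted mean zone index
`Σₖ k·fₖ ∈ [1, n]`.  It is linear in the profile, strictly increasing under
any outward transfer of mass, and invariant to the ordering of input rows.
The reference profiles give U251 ≈ 1.44 and U87 ≈ 2.44; a test population
is called *internal* below the inner reference (minus an optional margin,
default 0 — replicate noise is the reason a positive margin exists),
*external* above the outer reference, *intermediate* otherwise, ties being
non-internal.  Rankings sort ascending by score with lexicographic label
tie-breaks; the internal/external subgroup split is at the median rank
⌈n/2⌉ (the 4/4 split for eight lines), configurable.  Replicate wells are
scored per well and averaged per population; the spread is reported.

## Phenotype metrics

* **TMZ resistance** — trapezoidal mean viability over log10(dose), clipped
  to [0, 1].  Replicates are averaged per dose; a dose-0 row only
  normalises.  A normalised AUC is preferred over an IC50 fit because it
  stays defined for flat, fully resistant curves and for few doses.
  Negative doses are rejected (log scale).
* **Proliferation** — least-squares slope of ln(OD) vs time (h⁻¹); exact on
  noiseless exponentials and insensitive to seeding density, unlike an
  endpoint OD.  Non-positive readings are dropped; fewer than three usable
  points leave the metric missing.
* **Invasion** — relative invaded-area change (A₇₂ − A₀)/A₀; missing when
  A₀ = 0.

Phenotype rankings orient high values last (resistant / fast / invasive ↔
external) so that concordance with the spatial ranking is directly
interpretable.  Concordance is Spearman ρ on the rank vectors plus the
fraction of labels whose subgroup matches.

## Survival

Kaplan–Meier and the two-group log-rank test are implemented from the
product-limit and hypergeometric formulas (Greenwood variance included);
events are processed before censorings at tied times.  The unweighted
log-rank is the default comparison — the convention for KM group
comparisons — with Gehan–Wilcoxon weighting behind a flag; no
multiple-testing correction is applied by default (a Bonferroni helper
exists).  Cox regression and covariate adjustment are out of scope.
Correctness is checked against hand-computed fixtures to 1e-12 and against
lifelines on random data; Monte-Carlo calibration over 1,000 null
simulations (n = 50/group, 20% censoring) keeps the empirical type-I error
in [0.03, 0.07] at α = 0.05, with power > 0.8 at hazard ratio 3 and
n = 30/group.

## What the synthetic generators emulate — and what they do not

`generate_aggregate_image` renders each population as uniform-intensity,
anti-aliased disks (intensities add where cells overlap), with radial
placement either drawn from explicit per-zone occupancy probabilities or
from a core–shell model (shell probability `shell_bias`, core radius
`core_fraction`·R); placement within the chosen region is area-uniform, so
the probabilities are occupancy probabilities rather than center densities.
Cells crossing a zone boundary are placed by center; the quantifier alone
decides boundary pixels, keeping generator and measurement independent.
The 2D render is replicated across z-slices with independent additive
Gaussian noise (sd `noise_sd`, clipped at zero).  Defaults: 500-μm well,
1 μm/px, 5 zones.  Not emulated: adhesion-driven sorting dynamics (placement
is sampled directly from target distributions), optical PSF and confocal
noise statistics (the Gaussian default is a stand-in, not an instrument
claim), intra-cell texture, and cell–cell exclusion.  Passing tests
therefore demonstrate the measurement chain, not image realism.

`generate_phenotype_tables` draws dose–viability from a four-parameter
logistic (top 1, bottom 0.05, Hill 1.5) whose log half-effect dose rises
linearly from 10 μM to ≈3.2 mM with the min–max-normalised spatial score
when coupling is `resistant_when_external` (exact rank reproduction at zero
noise; equal scores give identical curves), or independently of the score
under `independent`.  The default dose grid spans 10–1000 μM — a
placeholder grid, as no canonical dosing scheme exists for this assay.
Growth (rate ~ U(0.01, 0.03) h⁻¹) and invasion (72-h fold gain ~ U(0.5, 3))
are always score-independent.  Noise is additive on viability and
multiplicative (1+ε) on OD and area so one `noise_sd` is meaningful across
metrics of different magnitude.

`generate_survival` draws exponential event times with baseline hazard
ln 2/`baseline_median` for the alphabetically first group and that hazard
times `hazard_ratio` for the second, censoring each record with probability
`censor_prob` uniformly on (0, event time).

## The zone-occupancy recovery experiment

The round-trip check (and `scripts/acceptance.py`) generates 2,000-cell
wells with the U251 (57/42/1/0/0%) and U87 (5/48/45/2/0%) reference
occupancies and re-measures them with the zonation module, requiring
agreement within 3 binomial standard errors per zone (±3.3 points at
p = 0.57, n = 2,000).

Pixel-area occupancy is a *biased* estimator of placement probability when
disks overlap: overlapping pixels are counted once, and zones of different
density saturate differently.  Under a Boolean coverage model the measured
area per zone scales as `A·(1 − e^(−λ))` for expected coverage λ; with
cell-sized disks (radius ≈ 6 μm) the inner zones of the U251 profile would
saturate outright.  The recovery experiment therefore uses sparse
sub-resolution markers — radius 0.5 μm at 0.25 μm/px with 5% additive noise
— keeping peak expected coverage near 0.11 and the closed-form saturation
bias (≈1 point in Zone I, less elsewhere) well inside the acceptance band.
These parameters follow from that calculation, not from tuning; realistic
cell-sized disks remain the default for demo imagery, where relative
ordering rather than unbiased occupancy is what matters.

## Numerical and interface choices

* All randomness flows from one top-level seed through `SeedSequence`
  substreams (child seeds < 2³¹); identical config + seed reproduce every
  numeric output bit-identically, and CSV bodies byte-identically when
  timestamps are disabled.
* Output CSVs carry `# key=value` provenance headers (version, seed, config
  hash); readers skip `#` lines.  JSON reports carry a schema version.
* Degenerate inputs are warnings or missing values, never silent zeros:
  empty channels, non-positive ODs, zero starting invasion area and
  unscored labels propagate as missing with reduced-n ranking.
* The CLI (`hma simulate | zonate | score | phenotype | correlate | survive
  | run`) is a thin layer over the library; exit codes are 0 (ok),
  2 (configuration error), 3 (data error).  Plots are not produced; all
  outputs are diff-able CSV/JSON.

## Known limitations

* Whether the original zones were equal-width or equal-area, and how wells
  were registered, is not documented for this assay family; equal width and
  the intensity centroid are this package's defaults, both configurable.
  A spherical-shell (3D) variant around the aggregate centroid would be a
  natural extension; the cylindrical version is what is implemented.
* The scalarisation of a zone profile (weighted mean zone index) and of a
  dose–response curve (normalised log-dose AUC) are this package's choices;
  they reproduce the qualitative orderings the assay relies on but are not
  the only defensible statistics.
* Real patient survival cannot be reproduced from synthetic cohorts; the
  survival module demonstrates calibration and power on generated data
  only.
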