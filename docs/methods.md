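# Methods

## The analysis problem

Sparse colony-forming-unit (CFU) assays of bone marrow stromal cells (BMSCs)
are commonly read out as "one colony = one clonal stem-cell progeny".
Time-lapse imaging at 15-minute intervals makes that assumption testable:
each segmented frame yields per-cell labels, tracking links them across
frames, and the resulting lineage forest supports operational definitions of
senescence, proliferative capacity, twin asynchrony and colony origin.
`clonoscope` implements that analysis layer, plus an agent-based generator of
synthetic experiments with the same statistical structure, so every stage can
be exercised and validated end to end without terabyte-scale raw images.

## The tracking exchange format

The canonical input is the *object-number matrix*: a frames x cells integer
table in which entry (t, c) is the per-frame segmentation label of cell c at
frame t, and 0 means the cell does not exist. A valid matrix satisfies two
structural rules: each column's support is a single contiguous frame
interval, and a column that ends at frame t (a division) is matched by
exactly two columns that begin at frame t+1 (the daughters).
`lineage.validate_matrix` reports every violation as a finding — `gap`
(zeros inside a support), `merge` (fewer than two successors), `orphan`
(a surplus starter at a division boundary) — and `sim_colony.corrupt_matrix`
can inject exactly these error classes for testing curation workflows.
Columns that begin mid-experiment at a frame where no column ended are
treated as migrating-in founders (generation 1, undefined lifetime), not as
errors.

When two or more divisions end at the same frame, daughters are attributed
to parents by minimising the summed distance between parent end-centroids
and daughter start-centroids (Hungarian assignment over two slots per
parent). This requires centroids; without them the ambiguity is reported as
an error rather than guessed.

## Genealogy conventions

* Generation is 1 for founders and increments at each division.
* Lifetime spans both endpoint frames: `(last - birth + 1) * dt`. At 15-min
  frames a cell spanning 96 frames has lifetime 1.0 d. The convention is a
  choice — the alternative (`last - birth`) differs by one frame (0.0104 d),
  well below every tolerance used here — and is documented rather than
  configurable per call.
* Lifetime is undefined for founders (birth precedes observation) and for
  cells with no documented division; undefined values are masked out of all
  lifetime statistics.

## The synthetic colony model

Each cell is an agent with a birth frame, a stochastic fate, a spread-area
trajectory and a migration trajectory.

**Cell-cycle times.** Dividing-cell lifetimes are drawn from a normal
distribution truncated at one frame. The truncation point is the only hard
constraint the data format imposes; a two-parameter family is the minimal
choice that can match a reported mean and SD (defaults 0.83 d and 0.27 d).
Founders add a fixed first-generation lag (default 1.0 d) to their draw,
reflecting the long post-plating growth phase of freshly passaged cells.

**Senescence.** Each non-founder daughter independently becomes senescent
with probability `p_senescent_daughter`. Senescent cells never divide and
keep growing in area at `senescent_growth_rate_um2_per_d`. No mechanism is
claimed; an i.i.d. Bernoulli is the weakest assumption that produces the
observed mixture of arrested and proliferating cells. The default
p = 0.08 was calibrated once, on 750 simulated colonies across three seed
families, so that the mean per-colony fraction of Day-4 cells not dividing
by Day 7 is approximately 16%. The per-colony fraction is strongly
right-skewed (an early division with two senescent daughters arrests a
whole colony near 100%), which is why the calibration used large samples;
its per-colony SD (~15 percentage points) is close to the reported
between-colony spread.

**Spread area.** A founder is born at `area_birth_um2` (default 3500 um^2).
Area grows linearly at `area_growth_rate_um2_per_d` while a cell lives; at
division each daughter starts at
`generation_shrink_factor * parent_area / 2` (default factor 0.9), so no
area is created at division and birth areas decay geometrically toward a
steady state of a few thousand um^2 — producing the decreasing area-vs-
generation trend within progenies. Growth (4600 um^2/d) and migration (below)
were calibrated jointly, once, to the reported Day-7 whole-colony summaries
(mean confluency ~12.7%, mean approximate diameter ~1.9 mm).

**Migration.** Cells perform a persistent random walk: the per-frame
velocity is an AR(1) process with autocorrelation `migration_persistence`
(default 0.6) and stationary per-axis step SD `migration_step_sd_um`
(default 13.5 um/frame, i.e. ~50 um/h of instantaneous speed), reflected at
the field borders. Daughters are placed one cell radius apart along a
uniformly random axis.

**Media exchange.** Exchanges default to frame 374 and then twice weekly.
Each exchange inflates the variability of subsequent lifetime and
birth-area draws by a multiplicative log-normal factor
(`media_perturbation_sd`, default 0.15 per exchange, combined in
quadrature). The real perturbation is only known to coincide with
diversification of previously uniform progenies; its magnitude is a free
parameter and is flagged as such.

**Field and seeding.** The default field is 4.3 x 3.3 mm (the fully expanded
five-by-five field-of-view grid) at 0.6467 um/px; at the default seeding
density of 30 cells/cm^2 this hosts 4 founders. Parameter-recovery
experiments use `n_founders = 1` so each experiment is one colony.

**Rendering.** Label images draw each living cell as a filled ellipse of its
current area (aspect ratio 2.5, fixed random orientation per cell) with the
per-frame object number as the label. Contested pixels go to the nearer
centroid and every living cell keeps at least one pixel, mimicking a
watershed-style segmentation of touching cells.

**What the generator does not emulate.** No cell death or field exit; no
contact inhibition or crowding effects on cycle time; no heritability of
cycle time or senescence within lineages beyond the media-exchange shift;
elliptical cell shapes rather than spread morphologies; no photometric
artifacts (halos, shading) — segmentation is taken as solved. Passing
recovery tests therefore validates the *analysis* pipeline and the internal
consistency of the calibration, not the biological fidelity of the model.

## Measurements

Per-frame geometry uses `skimage.measure.regionprops` (area, perimeter,
axis lengths, eccentricity, orientation, solidity, extent), with form factor
`4*pi*A/P^2` and compactness its reciprocal. Coordinates are 0-based pixel
indices, origin top-left, x along columns; all quantities carry both pixel
and micron units.

Neighbour statistics follow the 15-pixel (9.7 um) contact rule: two objects
are neighbours when their minimum edge-to-edge distance is at most the
threshold. Edge-to-edge distance is computed between boundary-pixel centres
minus one pixel, so two squares separated by a 10-pixel empty gap are 10 px
apart; it is floored at zero for touching objects.

Whole-colony metrics take the convex hull over the outer corners of all
member pixels (guaranteeing occupied area <= hull area, i.e. confluency <= 1),
occupied area as the member pixel count, confluency as their ratio, and the
approximate diameter as the equal-area circle diameter `2*sqrt(hull/pi)`.
The colony centroid is the unweighted mean of member object centroids. A
position-only mode (hull over centroids) exists for track data without
images and is flagged in its output, since it understates the hull by about
one cell radius along the rim.

The per-cell feature table aggregates lifetime averages, birth-time values
and derived genealogy quantities. Two windows matter: the early-area window
(first 0.83 d of a cell's record, 80 frames at 15-min sampling, rounded to
the nearest frame), which keeps long-lived low-generation cells from
dominating area trends; and the pre-division window (frames 4-8 before the
division, i.e. 1-2 h), over which the pre-division area is the arithmetic
mean. Validity masks implement the filter rules: lifetime columns masked
when lifetime is undefined; parent-derived columns masked for generations
1-2; division-conditioned columns masked for non-dividers. Masked entries
are excluded from every downstream statistic.

## Classifications

* **Fate**: a cell alive at the Day-4 reference frame (374) is senescent iff
  it does not divide by the Day-7 horizon (672); proliferative otherwise. A
  track that ends before the horizon without a division is *censored* and
  excluded from senescent fractions — the original design tracked every cell
  through the horizon, so censoring is a safe generalisation for shorter
  runs.
* **Proliferative class** of a progeny at Day 4: slow < 8 cells (under three
  population doublings), moderate 8-16, fast > 16 (over four doublings);
  boundaries inclusive at 8 and 16.
* **Twin asynchrony**: sibling lifetimes differing by strictly more than one
  dataset-wide SD of dividing-cell lifetime (auto-estimated, or supplied,
  e.g. 0.27 d).
* **Origin**: SCD when exactly one founder progeny forms the colony, MCD
  otherwise; roots whose track begins after frame 0 flag infiltration.
* **Colony predicate**: at least 50 cells.
* **Isolation score** 1-5 from the earliest time a foreign cell appears in
  each of the three monitored field-of-view sizes (1.7x1.3, 2.6x2.1,
  3.5x2.6 mm; expansions at Days 0, 2, 6).

## Statistics

Spearman's r_s is computed from midranks (tie-corrected) as the Pearson
correlation of rank vectors. Its two-sided p-value uses the exact
permutation distribution for n <= 9 and the t approximation
`t = r*sqrt((n-2)/(1-r^2))` above; the cut-over makes small-progeny trend
p-values exact and reproducible regardless of library defaults. Bonferroni
thresholds are always alpha/m for the m comparisons actually evaluated
(0.05/276 ~= 1.8e-4 for the 24-property single-cell screen; 0.05/105 ~= 5e-4
for the 14-property whole-colony screen). The critical |r_s| for the
whole-colony screen is an optional user input (a published table value,
0.619 for n = 28), not derived internally.

Group comparisons use Welch's unequal-variance t-test with per-filter
Bonferroni thresholds: alpha divided by the number of properties sharing a
validity filter (e.g. 0.05/3 for the three parent-derived properties).

PCA operates on the z-scored table (sample SD, so component variances sum to
the number of retained columns); rows with any masked or missing value in
the selected columns are dropped, and constant columns removed. k-means uses
k = round(sqrt(N/2)) by default — for the pooled 1384-cell dataset that
reading gives k = 26; the alternative reading sqrt(N)/2 = 19 was rejected as
inconsistent with "square-root of N divided by 2" — with 10 restarts from a
fixed seed, keeping the best inertia.

## Parameter recovery and problem sizes

`clonoscope.calibration` (driven by `scripts/acceptance.py`) simulates 100
independent single-founder experiments through Day 7 (frames 0-672),
exports each tracking matrix, rebuilds the forest, and recovers:

* dividing-cell lifetime mean and SD, pooled over cells born by frame 374
  whose divisions are documented by frame 672. Restricting to the
  single-cell-window population while tracking divisions through Day 7
  avoids right-censoring: in an exponentially growing population most cells
  are born near the end of the window, and a hard Day-4 cut-off would bias
  the mean low by about 0.1 d;
* the mean per-colony Day-4 senescent fraction via the fate classifier;
* mean Day-7 confluency and approximate diameter from rendered label images
  via the hull metrics.

One hundred colonies keep the seed-to-seed standard error of the senescent-
fraction mean near 1.5 percentage points (the dominant uncertainty: the
per-colony fraction has a ~15 pp SD, so small samples of colonies wander;
the confluency and diameter means are stable to ~0.4 pp and ~0.04 mm).  The
whole recovery completes in a few minutes on one CPU.

## Known limitations

* The lifetime distribution family (truncated normal) is a modelling choice
  constrained only by two moments; real cycle-time distributions are often
  right-skewed. The sampler is pluggable in principle via configuration of
  mean/SD but the family itself is fixed.
* Senescence is memoryless and unheritable; reported senescent-daughter
  clustering in slow progenies is not reproduced.
* The neighbour-distance convention (boundary-centre distance minus one
  pixel) differs from exact Euclidean edge distance by up to ~0.4 px on
  diagonals.
* Position-mode hull metrics understate hull area for small colonies.
* The media-exchange effect size is a free parameter; only its timing is
  anchored.
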