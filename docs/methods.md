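# Methods

## Problem setting

DNA-SIP compares the buoyant-density distribution of each OTU's 16S
sequences between an isotopically labeled incubation and a paired unlabeled
control. Because native density varies with G+C content, absolute density
alone cannot identify label uptake; the inference is always differential:
did this OTU's sequences move into the heavy end of the gradient *relative
to its own behavior without label*. `sipdetect` implements that inference
(the high-resolution SIP, "HRSIP", style of analysis) plus a generative
model of the experiment so that the detector's operating characteristics
can be measured against known truth.

## Density calibration

Fraction densities come from refractometry via a linear standard curve
BD = a·RI + b, fitted by unweighted ordinary least squares on a CsCl
dilution series (≥2 standards with distinct RI; a zero slope or coincident
RIs raise a degenerate-fit error). The reported `r` is the Pearson
correlation of (RI, density); no p-value is computed because nothing
downstream consumes it. Coefficients are kept at full precision; a bundled
default model (slope 10.302, intercept −12.747 g/ml) serves users without a
standards file. Out-of-range predicted densities (outside 1.0–2.0 g/ml) are
logged as warnings rather than errors: a misread refractometer is the
likely cause and the analyst should see the number. Temperature or salt
corrections and nonlinear calibrations are out of scope.

## Gradient and banding model

One gradient is `n_fractions` equal-width density bins spanning
[`bd_min`, `bd_max`] (defaults 12 bins over 1.674–1.737 g/ml, the mean CsCl
loading density being 1.725 g/ml). Fraction 1 is the heaviest, matching
collection order from the tube bottom; fraction metadata always carries
explicit bin-center densities so downstream code never relies on index
order.

Each OTU's DNA bands as a Gaussian in density:

* native center: 1.660 + 0.098·GC g/ml (classical unlabeled-DNA relation);
* label shift: 0.036·afe¹³C + 0.016·afe¹⁵N g/ml, linear in the DNA
  atom-fraction excess, recovering the classical full-substitution shifts
  at afe = 1;
* band width: common `band_sd` (default 0.006 g/ml), chosen so that
  unlabeled and fully ¹³C-labeled bands overlap partially across the
  12-fraction grid. Within-OTU GC heterogeneity and diffusion are not
  modeled separately.

All four density constants and the band width are configuration
(`IsotopeDensityModel`, `GradientConfig`), not code.

The Gaussian is integrated over the bins and renormalized over the
collected range. A `carryover` share of every OTU's mass (default 0.02) is
spread uniformly over all fractions. This emulates the well-known smear of
real gradients — every fraction of a real SIP gradient yields amplifiable
DNA of essentially all taxa (diffusion, sheared fragments, tube-wall
carryover) — and it is the reason paired controls are informative at all:
without it, fractions beyond every band's tail would have their
(multinomial, fixed-depth) read composition dominated by numerical
tails-of-tails, which no real library preparation would produce.

Sequencing is multinomial per fraction at fixed `depth_per_fraction`
(default 30,000 reads), optionally jittered lognormally. Control gradients
reuse the labeled slurry's composition by default; an optional Dirichlet
`composition_jitter` (concentration parameter; smaller = rougher) emulates
between-slurry compositional drift — the failure mode the light-window
criterion guards against.

### Default community

`make_community` draws lognormal relative abundances (σ = 1.5 on the log
scale, normalized), uniform GC in (0.26, 0.40), and assigns a configurable
fraction of OTUs the scenario's atom-fraction-excess caps (PAOM 0.15/0.09,
protein 0.18/0.07, acetate 0.50/0.0) scaled by an `assimilation_efficiency`
multiplier (default 1.0; the attainable DNA labeling from a partially
labeled substrate is not knowable in advance, so it is exposed rather than
asserted). The GC default places native band centers at 1.685–1.699 g/ml,
below the 1.70 g/ml heavy threshold — the premise of the single-window
design, which chooses the threshold above the bulk unlabeled community.
Organisms whose native density already exceeds the threshold are
structurally invisible to single-window HRSIP (their heavy window cannot be
further enriched); the generator deliberately does not produce them by
default, and passing a wider `gc_range` shows exactly that blind spot.

### What the simulator does not emulate

PCR and primer bias, chimeras, per-taxon 16S copy number, rotor
hydrodynamics and time-to-equilibrium, within-OTU GC variance, and read-
level error. Passing tests therefore demonstrate the statistical machinery
under the stated generative model, not performance on any particular real
dataset.

## Preprocessing

Three hygiene rules in a fixed order — singletons (table-wide total exactly
1), blocked taxa (case-insensitive exact token match at any rank; default
Cyanobacteria, indistinguishable from substrate-carried DNA when the
substrate is algal biomass), then a strict (<) 0.005% relative-abundance
floor computed over the whole table's grand total (a per-gradient mode is a
flag). The retained set is order-independent; only the attribution of each
removal to a rule depends on the order, so the order is fixed for
reproducible reports. The filter report must reconcile
(input = retained + Σ removals) by construction.

## Detection

* **Windows.** Heavy = buoyant density strictly > 1.70 g/ml (7 of the 12
  default fractions); light = complement (the analysis never bounds light
  from below). A gradient with an empty window is an error, not a silent
  skip.
* **Normalization.** Median-of-ratios size factors per tested sample
  subset, rescaled to geometric mean 1. When no OTU is positive in all
  samples the reference falls back to OTUs positive in ≥50% of samples,
  then to library-size factors, each with a logged warning.
* **Dispersion.** Per-OTU method-of-moments on the pooled within-group
  variance of normalized counts, shrunk 50/50 toward a trend
  α ≈ a₀ + a₁/μ fitted across OTUs (coefficients clipped at 0), floored at
  1e−8; non-positive moment estimates fall back to the trend. This is
  deliberately simpler than reference-grade shrinkage (no Cox–Reid
  adjustment, no MAP): the contract is the simulation-calibrated FDR and
  sensitivity, not numeric identity with any other implementation. Note
  that banding structure across fractions *is* within-group variance under
  the fractions-as-replicates design, so dispersions are large for OTUs
  whose band spans a window; this is faithful to the design, and it is why
  detected OTUs need large fold changes.
* **Test.** Per OTU, l2fc = log₂(μ_labeled/μ_control) of window group
  means; Wald statistic (l2fc − 0.25)/se with the delta-method standard
  error from NB variance μ + αμ²; one-sided p for l2fc > 0.25. The 0.25
  null follows the published HRSIP convention; it is a prominent flag and
  echoed in `run_config.yaml`. A zero *window* mean for an OTU present in
  both incubations gets a +0.5 pseudo-mean; zero reads across an entire
  incubation mark the OTU untested (no statistics, never labeled, reason
  recorded).
* **Multiplicity.** BH step-up within each (comparison, window) family over
  tested OTUs only; heavy and light families are adjusted separately (the
  two criteria are separate tests). FDR threshold 0.10.
* **Verdict.** labeled = criterion 1 (heavy padj < FDR) AND NOT criterion 2
  violated (light padj < FDR). Criterion 2's test is one-sided in the same
  direction (labeled > control), the natural reading of "not significantly
  more abundant".

### Known limitations

* High-GC OTUs (native density above the threshold) cannot be detected;
  multi-window scans (MW-HR-SIP) and quantitative qSIP are out of scope.
* Criterion 2's power to reject a *lone* compositional shifter is limited:
  one truly enriched OTU inside a BH family of nulls needs a raw light-
  window p below roughly FDR/m, so on noisy backgrounds a single 4×
  whole-gradient shifter escapes the guard in a sizable share of runs. The
  guard is sharp when the light-window test is precise (low dispersion) or
  when compositional drift affects many OTUs at once.
* Fractions are pseudo-replicates of one biological slurry per gradient;
  inference is about this incubation pair, not a population of slurries.

## Numerical choices

* Band masses renormalize over the collected range; a band centered
  entirely outside it collapses to the nearest edge fraction.
* The BH implementation excludes untested (NaN) entries from the family
  size and propagates NaN, and matches the brute-force step-up definition
  exactly (tested on 1,000 random vectors).
* Simulation, detection and the pipeline are deterministic given a seed;
  reruns are byte-identical.
* Simulation sizes used in the test suite and acceptance script (200 OTUs,
  20 replicates, 30,000 reads/fraction) were chosen as the smallest
  configuration at which the realized-FDR and sensitivity estimates are
  stable across seeds.

## Reporting

Per-taxon summaries count labeled OTUs at a chosen rank and express their
reads as a percentage of the labeled gradient's post-filter grand total
across all fractions (a flag pools labeled+control denominators; OTUs
unassigned at the rank aggregate under "unclassified"). The fold-change
matrix pivots heavy-window l2fc to OTUs × comparisons with untested cells
missing, not zero. The pipeline writes all tables as TSV plus a
`run_config.yaml` parameter echo and a `key=value` structured log so
reported counts can be parsed back programmatically.
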