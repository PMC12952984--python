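# Methods

## The geometric event-count model

The model treats each at-risk person as accruing autoimmune events with a
constant chance *X* ∈ [0, 1]: the probability of at least *p* events is the
survival function CE<sub>p</sub> = *X*<sup>p</sup>, so the exact-count
fraction is f<sub>p</sub> = *X*<sup>p</sup>(1 − *X*) untruncated, or
*X*<sup>p</sup>/Σ<sub>q=0..P</sub>*X*<sup>q</sup> when the event count is
capped at *P*. The survival reading is the one consistent with the
canonical worked example at *X* = 0.5 (25% / 12.5% / 6.25% / 6.25% for
"primary only" / one / two / three-or-more additional events), and
`one_fraction` is, by construction, the difference of consecutive
`one_survival` values (tested to 1e-12).

Defaults: `truncation_P = 12` (the event-count cap carried over from the
colonoscopy polyp-count convention in which the model family originated)
and `display_P = 5` (six or more autoimmune events in one person are
rare, so reports display p = 0–5). When the zero-event category is
unobservable (the primary condition is not itself an autoimmune disease,
or only persons with ≥ 1 additional event are tabulated), fractions are
renormalised over p ≥ 1 ("zero-truncated").

### Estimators

The exact estimator used in the model family's source literature is not
restated there, so four are provided and reported side by side:

- **loglinear** (default): slope of the simple linear regression of
  log₁₀ n<sub>p</sub> on p; X̂ = 10^slope. An exponential decay is exactly
  linear after the log transform, which matches the way the model is
  usually diagnosed, hence the default.
- **survival**: X̂ = fraction of persons with ≥ 1 event. Requires the
  zero category. Unbiased and tight at cohort sizes (MC s.e.
  √(X(1−X)/N) ≈ 0.0016 at N = 10⁵).
- **mean**: inverts the truncated-geometric mean event count (Brent root
  find on a monotone function).
- **grid**: least squares between observed counts and the geometric
  profile renormalised over the *observed* support, over X ∈ (0, 1) at
  step 1e-4. Normalising over the observed support (rather than the full
  truncation range) makes the grid optimum coincide with the log-linear
  estimate on exactly geometric tables, which is the estimator-equivalence
  property the test suite checks; on real tables the two normalisations
  differ by ~1e-3 in X̂.

Fit quality is reported two ways, since both appear in practice: the
Pearson correlation between observed and expected counts on the linear
scale over the displayed categories (with the reporting convention that a
PCC above 0.9995 is rounded up to 1), and the R² of the log₁₀ regression.
Fewer than three non-zero categories is a refuse-to-fit error (any model
fits two points); a single occupied category is a degenerate-distribution
error.

### Integer reconstruction from totals

Some studies print only the number of persons with ≥ 1 event and the
total event count. `reconstruct_distribution` enumerates every
non-increasing integer vector n₁..n_maxp satisfying both totals exactly
and returns the one with least squared deviation from its own
best-fitting geometric profile (grid step 1e-4, truncation-range
normalisation, ties broken by lexicographically largest n₁). The
enumeration is exhaustive, so the result is deterministic; for the
(56 persons, 85 events, max 5) case there are 51 feasible vectors and the
objective selects (36, 13, 5, 2, 0). The printed five-category split
circulating for that dataset ({38, 11, 4, 2, 1}) is feasible — both
totals hold — but is not the optimum of this objective; it sits fourth,
which is consistent with it having been stated as a plausible fit rather
than derived by explicit optimisation.

## Linear prevalence

Cumulative prevalence is fitted by ordinary least squares against time
(statsmodels OLS). Reported quantities: slope (incidence per year),
intercept, R², onset shift = −intercept/slope (the x-intercept, an
onset-plus-recognition delay in years) and years-to-full =
(1 − intercept)/slope, the extrapolated horizon at which the fitted line
reaches a cumulative fraction of one. Both derived quantities are NaN
(flagged, not raised) when the slope is not positive. For
age-at-diagnosis series the default fitting window caps at age 60, where
incidence starts to decline with immune-system ageing; interval series
are fitted in full. `incidence_from_prevalence` returns first differences
over time gaps and summarises their constancy by coefficient of
variation.

## Hotspot scanning

RGYW (R = A/G, G, Y = C/T, W = A/T) is scanned as a 4-mer core;
"one mismatch" means exactly one of the four positions violates its
class. Exact cores are reported as exact even when the scanner allows a
mismatch. The display convention shows five nucleotides (one 5′ flanking
base plus the core) because that is how such hotspots are conventionally
displayed; the core interval is authoritative for membership. GC-rich
runs are maximal runs of ≥ 9 consecutive G/C. The "other" category is a
user-configurable literal-motif list (default empty) — the grey
"exact-amino-acid/other" convention is not a derivable motif class.
Scanning is forward-strand; the reverse-complement relationship
(RGYW on the reverse strand ≡ WRCY forward) is a tested property, not a
default behaviour, since annotation figures mark the sense strand.

Coordinates are 1-based inclusive in an external system anchored by
`coord_offset` (e.g. CDS position); BED export is the single 0-based
half-open surface. Mutation membership resolves to the highest-priority
overlapping annotation (exact > mismatch > other > GC-rich). Codon
consequences use the standard genetic code via Biopython with codon index
⌈position/3⌉.

### Sequence fixtures

The two bundled gene-region fixtures (PLB1 exon-33-like, COPA
exon-8/9-like) are **synthetic**: the corresponding published figures are
not available as machine-readable sequence, so the fixtures are
constructed to satisfy every stated constraint instead — for the PLB1
region, exactly two exact-RGYW hotspots, the second being wild-type TGGCT
whose G>C mutation at CDS 2263 yields G755R (GGC→CGC) and the mutated
locus TCGCT; for the COPA region, seven SHM hotspots of which the first
four cover nucleotides 690–722, a GC run ≥ 9, and ten mutations with
seven inside the first four hotspots. Background composition and exact
feature spacing beyond those constraints are arbitrary, so the fixtures
exercise the code paths and the stated counts, nothing else.

## Pedigree penetrance

Model: one founder carries the trait; each child of a carrier inherits it
with probability ½ (`transmission`); spouses marrying in are non-carriers
(the trait is extremely rare; configurable); a carrier develops disease
with lifetime chance *X*, independently. Penetrance is age-independent in
this module — age-resolved penetrance lives in the two-hit module.

The affected-count pmf is exact: each member's subtree distribution is
computed conditional on the member's carrier state and convolved across
children (generating-function recursion, cached per (member, state)).
This requires every member to have at most one potential-carrier parent —
true for marry-in pedigrees; structures that defeat it (inbreeding
loops) fall back to Monte Carlo with a warning. The Monte Carlo twin is
vectorised over replicates and doubles as an independent cross-check:
exact vs 10⁵ replicates agree to total variation < 0.005 on the bundled
family at X = 0.333. Expected affected = Σ carrier-probability × X is
checked against the pmf mean to 1e-10.

The bundled four-generation family fixture encodes the published
generation sizes (12/19/9 at-risk members, one founder carrier, eight
observed affected, one antibody-positive member); the assignment of
children to couples is synthetic ({4,4,3,3,3,2} in generation III,
{3,2,2,2} in generation IV) because the real structure is figure-only.
All tested quantities (exact-vs-MC agreement, the expectation identity)
are structure-generic. No published probability criterion defines the
"4 to 10 affected expected" interval, so the package reports the full
pmf, the interval mass P(4 ≤ affected ≤ 10) ≈ 0.54 and the modal count
rather than asserting an interval.

Generation-skip probabilities (affected child, both parents unaffected,
trait descending through a carrier parent) are computed by exhaustive
enumeration over the carrier states of the member's ancestor closure —
exact for any loop-free ancestry, and cross-checked against a closed form
on a three-generation chain.

## Two-hit calculus

`second_hit_interval = per_locus_interval / hotspot_count`: with k
mutation-prone loci each sustaining a critical mutation once per interval,
disease-initiating hits arrive k times as often (k = 4 at 100 y/locus →
25 y; k = 7 → ~14 y). `biallelic_coincidence_rarity = susceptible_cells ×
interval²` reproduces the back-of-envelope bookkeeping literally (10⁶
cells × 100² = 10¹⁰ "persons") rather than re-deriving a hazard model;
the dimensional caveat ships with the number (`RARITY_DIMENSION_NOTE`)
because cells × years² is not literally persons. Age-resolved penetrance
defaults to the linear reading min(age·k/interval, 1) — matching the
constant-incidence picture (one event per 120 patient-years ⇒ 33% by age
40) — with a constant-hazard exponential alternative; the two agree
within 5% whenever age·k/interval ≤ 0.1 (first-order Taylor agreement,
tested).

## Synthetic generators

All generators are deterministic given a seed (NumPy `default_rng`).

- **Cohorts** draw N multinomial samples from the truncated geometric
  fractions (zero-truncated variant excludes p = 0 from the support);
  `exact=True` returns the largest-remainder-rounded expectation instead,
  for estimator-recovery checks without Monte Carlo noise.
- **Prevalence series**: cumulative = max(0, slope·(t − onset)) plus
  additive Gaussian noise, clamped to [0, 1] and monotonised with a
  running maximum (a cumulative series cannot decrease; the
  monotonisation bias is negligible at the default noise sd 0.005).
- **Pedigrees**: regular marry-in trees with one founder carrier.
- **Planted-motif sequences**: features are placed with ≥ 4 background
  bases of spacing and the background is resampled by a constraint walk
  (offending bases of any unplanned exact *or one-mismatch* RGYW window,
  over-long GC run, or stray literal motif are redrawn until the scan is
  clean). Forbidding one-mismatch windows is what makes planted-recovery
  tests exact: in uniform random DNA ~19% of windows are within one
  mismatch of RGYW, so naive rejection of whole sequences would never
  terminate. Two sampled-feature patterns are rejected at generation time
  because no background base can defuse their flanking window (a core
  with suffix [AG]G[CT] or prefix G[CT][AT], and GC runs whose last three
  bases carry fewer than two class violations); with those exclusions the
  walk converges in well under 100 iterations in practice, and a fresh
  placement is retried on the rare failure before raising a packing
  error.

### What the generators do and do not emulate

They reproduce the *models* the analyses assume — geometric counts,
linear onset, Bernoulli transmission/penetrance, motif-planted DNA — with
known ground truth. They do not emulate registry realities: diagnostic
drift, cohort censoring, age structure, correlated events within persons,
or realistic genomic base composition. Passing recovery tests therefore
demonstrates correctness of the estimators and scanners under their own
assumptions, not robustness to real-data artefacts. Published
registry-scale results (prevalence R² > 0.99 across national cohorts;
per-disease PCCs of 0.998–1) depend on data that exist only as figures
and are represented here by generate-then-fit recovery at matched
parameter scales (slope 1/150, onset 17 y, noise sd 0.005, n = 40;
cohorts X ∈ {0.1, 0.3, 0.5}, N = 10⁵).

## Problem sizes and numerical choices

Monte Carlo cross-checks use 10⁵ replicates (total-variation tolerance
0.01 sits > 4 MC standard errors from the observed ≈ 0.002); scanner
oracle equivalence uses 1,000 random 60-mers; planted recovery 50 seeds;
grid estimators use step 1e-4. Normalisation identities are asserted at
1e-12, expectation identities at 1e-10 relative. These sizes keep the
full suite under a few seconds while leaving every tolerance several
multiples above observed error.

## Known limitations

- The geometric fit assumes a single constant event chance per cohort;
  mixtures of X across subpopulations are not modelled.
- The exact pedigree recursion does not handle inbreeding loops (it
  falls back to Monte Carlo), and penetrance there is age-independent.
- The two-hit rarity figure is bookkeeping, not a dimensional hazard
  model; treat its units as nominal.
- Hotspot scanning is motif-based only; it does not model AID targeting
  biochemistry, strand bias, or genome-wide context.
- The bundled sequence and family fixtures are synthetic stand-ins
  constrained by published counts, not published primary data.
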