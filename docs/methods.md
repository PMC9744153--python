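# Methods

## The extended CST model

`vagcst` classifies vaginal communities by a dominance rule evaluated at a
fixed working rank: genus level for all taxa except *Lactobacillus*, which
is split into species (the classical CST I/II/III/V distinction is a
species-level one — a genus-aggregated *Lactobacillus* test could not tell
an *L. crispatus* community with an *L. iners* minority from the reverse),
and *Gardnerella vaginalis*, kept at species level as the registry's single
*Gardnerella* entry. Species labels of any other genus fold into the genus
on canonicalization.

A sample's most abundant taxon (`top`, with RA `r`) determines its label.
The 50% dominance threshold is **inclusive** (`r ≥ 0.5` fires the
dominance branch); below it the sample is polymicrobial and falls into a
CST IV subtype keyed on the same argmax taxon (IV-A for *G. vaginalis*,
IV-B for the *Prevotella* group, IV-C otherwise — including sub-threshold
*Lactobacillus* tops). Dominant taxa map to I/II/III/V (canonical
lactobacilli), VI (*G. vaginalis*), VII (*Prevotella* group), VIII (THPP
panel) and IX (anything else). A dominant *Lactobacillus* species outside
the canonical four is biologically ambiguous and yields `UNRESOLVED`
unless the configuration folds it elsewhere.

Design choices where the scheme is genuinely open:

- **Ties at the argmax** (possible with rounded inputs) are broken by a
  fixed group priority — Lactobacillus > Gardnerella > Prevotella > THPP >
  other, then alphabetically — and noted in the assignment's rationale
  string. Any fixed order restores determinism; this one prefers the most
  clinically salient interpretation.
- **IV subtypes use a uniform < 50% boundary.** Published cluster
  descriptions occasionally quote narrower empirical ranges for a subtype
  (e.g. *Prevotella* ≤ 45% in IV-B); these are treated as observations,
  not rule boundaries.
- **Strict argmax in IV-A/IV-C.** Descriptions of some *G. vaginalis*-rich
  clusters admit compositions where *L. iners* slightly exceeds
  *G. vaginalis*; the implemented rule follows the argmax literally, so
  such a composition is IV-C. The bundled blueprint realizes those rows
  with the described head taxon strictly on top (see below).
- **Peptostreptococcus** is a THPP member for classification (it appears
  as a THPP-dominant cluster head), but the six-genus summary panel used
  for the overall pathobiont load (Streptococcus, Escherichia–Shigella,
  Enterococcus, Staphylococcus, Ureaplasma, Mycoplasma) excludes it;
  `panel_total` takes an explicit taxon list so both conventions are
  expressible.
- The default THPP registry covers the panel members nameable from the
  bundled survey's main tables; studies with a larger panel supply it via
  the registry file (tab-separated: name, rank, group; then an
  alias→canonical synonym section).

## Abundance handling

Tables are samples × taxa with a `counts`/`relative` mode flag. Reading
canonicalizes labels (case-, whitespace-, underscore- and dash-variant
insensitive) and sums columns that collapse onto one canonical taxon; mode
is auto-detected (rows summing to ~1 or ~100 are relative; percent tables
are rescaled). Relative rows must sum to 1 within 1e-6 (float hygiene;
stricter than needed for any real table).

Rarefaction draws a multivariate hypergeometric sample (subsampling
without replacement) to a fixed depth — 80,000 reads in the bundled
survey's protocol — dropping shallower samples with a warning. Group mean
profiles are arithmetic means of member RA vectors; the **overall profile
is the unweighted mean of the group profiles**, not the pooled per-sample
mean. This equal-weight convention is the one under which the bundled
summary's overall Lactobacillus RA (47.9%) equals the mean of its five
cohort values; the pooled mean remains available as an option. Whether to
rarefy before or after computing summary RAs is exposed as pipeline
ordering (the `run` command rarefies first when a depth is given).

## Diversity and group tests

Shannon diversity uses base-2 logarithms by default (bits; the common
amplicon-pipeline convention), with the base exposed. Beta diversity is
Bray–Curtis, `BC(x, y) = 1 − Σᵢ min(xᵢ, yᵢ)` for normalized vectors — a
bounded semimetric (the triangle inequality is not guaranteed and not
asserted). Phylogeny-dependent metrics (UniFrac) are out of scope since no
tree accompanies genus-level tables.

PERMANOVA is implemented as a permutation statistic: pseudo-F from
among/within sums of squared distances with `p = (1 + #{F_perm ≥ F_obs}) /
(1 + n_perm)`, free label permutation (no strata), default 999
permutations; the attainable floor is 1/(1+n_perm), and a permutation that
happens to reproduce the group partition ties F exactly. Tests validate
the statistic against scikit-bio's PERMANOVA and calibrate the null
rejection rate. Per-sample values are compared with a global
Kruskal–Wallis plus all pairwise tests; pairwise p-values get
Benjamini–Hochberg adjustment (the multiplicity correction is a package
choice; identical-value degenerate inputs return statistic 0, p 1).

## Correlation workflow

Aggregate variables are panel sums of RA per sample. Method choice is
data-driven: Shapiro–Wilk on each variable at α = 0.05; Pearson only when
both pass, Spearman otherwise (an override can force either). 95%
confidence intervals use the Fisher z transform for Pearson and a seeded
percentile bootstrap (2,000 resamples) for Spearman, whose sampling
distribution has no convenient closed form on tied, compositional data.
Bands: strong |r| ≥ 0.50, moderate 0.30–0.49, weak below. Constant
variables are rejected (or skipped with a warning in the CLI battery —
e.g. a pathobiont panel absent from an entire cohort). These are ordinary
bivariate statistics on compositional data; compositionality-aware
estimators (SparCC-style) are deliberately out of scope, and strong
negative dependences partly reflect the sum constraint.

## Synthetic cohorts

**Constraint realizer.** A `FixtureConstraint` holds per-taxon RA bounds
(`lo == hi` asserts an exact value) and the description's head taxon. The
realizer draws the head first (restricted above every co-taxon's lower
bound), then co-taxa uniformly below it, and spreads the remaining mass
over a heterogeneous pool (Sneathia, Megasphaera, Atopobium, Dialister,
... — no Lactobacillus/Gardnerella/Prevotella/THPP members, so the fill
can never change a label) with each fill taxon strictly below 7% and below
the head. One-sided bounds (">98.9%") are closed at a feasible upper
value; infeasible constraint sets (lower bounds summing past 100%) raise.
Outputs are validated against their own constraints and carry no labels.
The built-in blueprint encodes the bundled survey's 151 cluster-description
row instances with their per-cohort counts; classifying its realization
reproduces the survey's CST census for every seed because the census is
determined by the constraints, not the draw.

**Dirichlet-multinomial simulator.** Per sample: CST ~ its group's
frequency vector; composition ~ Dirichlet(concentration × archetype mean);
depth ~ negative binomial (default mean 120,000, dispersion 8 — read-count
overdispersion typical of amplicon runs); counts ~ multinomial. The
default group sizes and CST frequencies are the bundled survey's observed
census (e.g. the AA group is 50% CST I, 46% CST III); archetype mean
profiles put each CST's dominant taxon inside its described abundance
range (CST I: *L. crispatus* 0.90; IV-A: *G. vaginalis* 0.38; VIII:
*Streptococcus* 0.66; ...). Concentration defaults to 50, putting the
dominant taxon's standard deviation near 0.05–0.07 — enough noise that a
few percent of draws cross the 0.5 dominance boundary (the observed label
recovery at default settings is ~98%), while concentration → ∞ recovers
the archetypes exactly. The simulator emulates the statistical structure
the analyses assume, not real sequencing: no taxonomic misassignment,
chimeras, contamination, zero-inflation beyond the multinomial, or
temporal CST transitions — so passing recovery/calibration tests shows the
machinery is correct under the stated model, not that real cohorts meet
that model.

## Problem sizes and numerical notes

The validation suite runs the blueprint cohort at its native n = 151;
recovery experiments use 500 simulated samples at depth 50,000; null
calibrations use 500 replicates (99 permutations each for PERMANOVA);
CI-coverage checks use 500 bivariate-normal datasets of n = 50. All
randomness flows through `numpy.random.default_rng` seeds; identical seeds
give bit-identical tables, labels and intervals. Distance matrices are
checked symmetric with zero diagonal at 1e-12; compositions at 1e-6.

## Known limitations

- The default THPP panel is the main-table-derivable subset, not any
  study's full panel; registry files extend it.
- Correlations ignore compositional bias (see above).
- The classifier is a rule system, not a nearest-centroid classifier;
  samples outside the modeled taxon universe land in IV-C/IX by
  construction.
- Genus-level working rank hides species-level heterogeneity everywhere
  except *Lactobacillus* and *G. vaginalis*.
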