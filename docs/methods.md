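# Methods

## The use-report unit

Everything downstream counts *use-reports*: distinct
(informant, species, use-category) triples. Repeat mentions of different
ailments under the same category by the same informant collapse to one
unit; mentions in different categories are separate units; the
"at least two interviewees" multiplicity of classic use-report counting is
emergent from distinct-triple counting, not a separate filter.

This unit is forced by the published numbers themselves: per-species totals
(up to UR = 1134) exceed the informant total N = 335, which is only
possible when each informant can contribute one unit per category rather
than one per species. A corollary worth knowing: because a category count
UR_c is itself a count of distinct informants, the "alternative" cultural
importance reading that divides each category term by the informants citing
the plant *in that category* degenerates exactly to UC (the number of used
categories). It is implemented behind
`species_indices(..., civ_denominator="category_informants")` for
completeness but is not a headline output.

## Index conventions

* **UV = UR/N** with N the study-wide informant total, held in
  `StudyConfig.n_informants_total` (default 335).
* **CIV** divides by the number of informants reporting the plant
  (`informant_count` in the species-use matrix), per the printed formula.
* **UD** is Shannon entropy in nats (natural log), consistent with the
  printed per-species values all satisfying UD ≤ ln UC; the log base is an
  argument for users who prefer bits.
* **ICF** requires Nur ≥ 2 (it is undefined at a single report) and lives
  in [0, 1] by construction.
* **FL** is reported as a whole percent; 1 ≤ Ip ≤ Iu is enforced.
* **Jaccard**: the default variant is C/(A+B) because that is the formula
  the source tables print — note it equals 0.5, not 1, on identical lists.
  The classical C/(A+B−C) is selected with `variant="standard"`.
* **Report rounding** is half-up via decimal arithmetic (`round_half_up`),
  not banker's rounding: UV/CIV/UD/ICF and percentage shares to two
  decimals, FL to a whole percent. Full precision is kept everywhere except
  explicit "report" output.
* **Spearman matrix**: midranks for ties, computed pairwise; a
  zero-variance column has no rank order, and its cells are returned as
  NaN with a warning rather than an arbitrary 0.
* **rank_table** breaks ties on the species name ascending so that
  rankings are invariant under input permutation.

## Group comparisons

Two strata: two-sided Mann-Whitney U. Three or more: Kruskal-Wallis H.
Sidedness is not stated by the source; two-sided is the conservative
default. Small samples (≤ 200 000 arrangements) use an in-package exact
permutation enumeration over the U statistic, which handles ties without
approximation; larger samples use scipy's tie- and continuity-corrected
normal approximation. The asymptotic machinery is deliberately delegated
to scipy.stats — the module's own contract is the exact path and the
reporting structure (per-group n and medians, statistic, p, α = 0.01).

## Barcode identification ladder

* The score window is **inclusive** at exactly max − δ (δ = 5 bit-score
  points by default): a hit at precisely the boundary is "within" the
  deviation. The deviation unit is taken to be bit-score points of the
  hit's max score.
* "Top 5 hits" for the optimized score is read as the five best-scoring
  **distinct-taxon** hits (duplicate subject taxa collapsed to their best
  row); reading it as the score window instead is available via
  `optimized_call(..., mode="window")`.
* Optimized-score ties resolve to the higher max score, then higher
  identity, then input order — fully deterministic.
* Synonym normalization (authority stripping, case folding, an optional
  two-column synonym map) is applied before any species-set test, because
  real hit tables mix synonymous binomials.
* Consensus precedence is the package's own design, since the narrative
  description of the integration names no tie-break order: occurrence
  allow-list first (an unrecorded species candidate is **demoted to its
  genus**, not discarded — the generic affinity of the hit still stands),
  then the a-priori genus/family constraint, then acceptance of the most
  specific rank supported by ≥ 2 independent sources (a marker counts once
  across its simple and optimized calls; morphology and dictionary are one
  source each), and finally a lowest-common-rank fallback. Identical
  inputs give identical calls and provenance.

## Synthetic data

The generators stand in for the raw interview data, which are not
deposited. `gen_informants` draws the seven demographic variables
independently with the published marginal counts (no cross-tabulation is
published, so the joint is the product of marginals; the printed
male/female percentage pair is transposed in the original and the counts
are used instead). `gen_citations` gives informant i a negative binomial
raw citation count with mean `mean_citations` × (product of stratum
effects); a negative binomial rather than a Poisson because the published
stratum medians (92–189) are far too spread for Poisson noise. Species are
drawn by a rank power-law (exponent 0.8 spans the published ≈ 40× ratio
between most- and least-cited species), categories from a per-species
symmetric Dirichlet (concentration 0.1, which reproduces the published UC
range of roughly 1–12), and ailments from a weighted per-category list so
fidelity levels have realistic spread. Locality effects are flat by
default, matching the published null result for location, and each species
is available in all localities with probability 0.8 (published
locality-list overlaps are high, C/(A+B) ≈ 0.4). The base intensity
(205 raw citations) is calibrated so the median per-informant use-report
count after collapsing lands near the published ≈ 112.

What the generator does **not** emulate: correlations between demographic
variables, informant-specific category preferences, geographic structure
within a locality, and any informant–species affinity beyond popularity.
Passing tests therefore demonstrate correctness of the computations and
recoverability under the assumed design, not fidelity to any real
community's knowledge structure.

`gen_blast_hits` constructs the score window to realize one of five
ambiguity modes exactly (clean / congeneric / confamilial / cross-family /
none-amplified), with decoy hits at least 15 points below the window. All
generators run off `numpy.random.default_rng(seed)` only.

## Printed-table inconsistencies

The packaged reference tables are preserved exactly as printed, including
five internal inconsistencies that recomputation exposes
(`datasets.PRINTED_INCONSISTENCIES`):

* three per-species UV cells match truncation of UR/335 rather than
  half-up rounding, and one (row 118) is a typo irreconcilable with its
  own UR digit (printed 0.35 vs 0.49 recomputed);
* the DOS category prints ICF 0.99 where (2563−40)/2562 = 0.9848 → 0.98;
* the DRS use-report share prints 9.44 where 9.4455 → 9.45;
* the species-table UR total (41 246) and the category-table total
  (41 247) differ by one;
* one species row prints UC = 1 with UD = 0.69, impossible for a
  single-category entropy.

Tests pin each discrepancy to its exact printed/recomputed pair instead of
silently "fixing" the data or skipping the row.

## Problem sizes and numerical tolerances

The property suites run 100 seeded small surveys (20 informants × 12
species) against brute-force recomputation at 1e-9; barcode recovery runs
200 seeded replicates per ambiguity mode; the type-I calibration runs 1000
null surveys of 60 informants and accepts an empirical rate in
[0.002, 0.025] at α = 0.01, the two-sided exact binomial envelope around
the nominal rate. Spearman cells recomputed from the 2-dp rounded fixture
columns agree with the printed matrix to within 0.006; the UR–UV identity
is exact (ρ = 1) for UV recomputed as UR/335 and 1.00 after report
rounding for the printed column, whose rounding merges a few ranks.
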