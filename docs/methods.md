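# Methods

This note documents the models and numerical conventions behind each
module, the defaults of the synthetic-data generators, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Molecular graphs and perception

Molecules are heavy-atom graphs read from MDL V2000 molfiles (V3000 is
rejected with a clear error; coordinates are discarded, `M  CHG` blocks
applied). Three derived annotations are computed in a fixed order:

1. **Implicit hydrogens** — `max(0, default_valence + formal_charge −
   Σ bond orders)` with default valences C 4, N 3, O 2, F/Cl/Br/I 1, S 2,
   P 3. The additive charge adjustment covers common organic ions
   (tetravalent N⁺, monovalent O⁻). Over-valent atoms floor at zero with a
   logged warning rather than raising, so a malformed record degrades
   loudly but locally.
2. **Rings** — an edge is in-ring iff it is not a bridge; the ring list
   itself is a minimum cycle basis (networkx), each basis cycle re-ordered
   by traversal and ties broken by ring size then lowest atom index. Both
   views agree on membership and the construction is deterministic and
   permutation-invariant (property-tested).
3. **Aromaticity** — benzenoid-only: a six-membered C/N ring whose Kekulé
   bond orders alternate 1/2 is flagged aromatic. There is no Hückel
   electron counting and no five-membered heteroaromatic perception. This
   is sufficient for the biphenyl-carboxanilide chemotype the package was
   built around and for common drug-like fixtures; molecules with fused or
   five-membered aromatic systems will be under-flagged, which inflates
   fraction-Csp³ denominator correctness but can mis-classify TPSA
   environments (those raise rather than contribute silently).

## Descriptors

- **Molecular weight** uses IUPAC standard atomic weights at three
  decimals, summed exactly in decimal arithmetic and rounded half-up to
  two decimals.
- **Donors/acceptors** are the Lipinski counts: donors = hydrogens on N/O,
  acceptors = #N + #O. Halogens never count as acceptors — with four
  fluorines on the study compound this is the only reading consistent with
  its published acceptor count of 3.
- **TPSA** sums published Ertl fragment contributions over N/O atoms,
  classified by (element, charge, aromatic flag, #H, multiset of
  non-aromatic bond orders). An unmatched polar environment raises,
  listing the environment; a silent zero would corrupt the sum invisibly.
- **Fraction Csp³** = carbons with only single bonds and no aromatic flag,
  over all carbons; 0 for carbon-free molecules.
- **Rotatable bonds** are acyclic single bonds between two heavy atoms of
  degree ≥ 2, *including* amide C–N bonds. The stricter convention that
  excludes amides (e.g. RDKit's default) gives 3 for the study compound;
  the inclusive definition is the one consistent with its published count
  of 4, and the deviation is deliberate and documented.
- **Rule of five**: violations collected for MW ≥ 500, donors ≥ 5,
  acceptors ≥ 10, logP ≥ 5, molar refractivity outside [40, 130]. logP and
  molar refractivity come from external predictors (their models are
  proprietary to the prediction services); absent values skip those rules
  with a logged note instead of failing the verdict. Where two logP
  estimates exist for a compound (e.g. XLOGP3 4.87 vs a consensus 5.09),
  the caller chooses; the worked examples use the XLOGP3-style value.

## Dose–response endpoints

Percent growth is the standard piecewise normalization of the three
absorbance signals (time-zero Tz, control C, treated Ti); both branches
meet at PG = 0 when Ti = Tz (property-tested continuity). Endpoints are
the lowest concentrations where PG crosses +50 (GI50), 0 (TGI) and −50
(LC50), located by linear interpolation of PG against log₁₀ concentration
between the first bracketing dose pair. Interpolating in log rather than
linear concentration matches the ten-fold-spaced five-dose design; the
scheme is a documented choice, since only the defining levels are
standard. Under noise-induced non-monotonicity the first crossing from the
low-concentration side is reported — deterministic and conservative
(potency is never overstated by a later re-crossing). Unreached levels are
censored and serialize as `"> max"` / `"< min"` in µM.

## COMPARE fingerprints

Potencies are −log₁₀ of the molar endpoint; censored endpoints become
missing cells. Correlation is plain Pearson over the cell lines present in
both fingerprints (pairwise-complete; no imputation), rejected — not
errored — below a minimum overlap (default 25 common lines; real NCI60
comparisons run at ~44–57) or when a restricted vector is constant. The
ranking sorts by r descending, then overlap, then compound id.

## Target consensus

Predictor scores live on incomparable scales, so nothing mixes raw
numbers: within a predictor, targets rank by score (Pa−Pi for
activity-spectrum predictors, the probability, or the pharmacophore fit
score with z as tie-break) with average ranks for exact ties; across
predictors, targets order by how many predictors report them, then mean
reciprocal rank. Gene symbols are uppercased and trimmed before set
operations; alias resolution is out of scope (it would require an external
database and the upstream tools themselves use loose symbols).

## Genomics statistics

Co-occurrence enrichment splits the cohort by the index gene's alteration
status and compares every other gene between groups. The log₂ ratio is
computed from the *group percentages* — not raw counts — so published
tables that print only percentages can be reproduced without the group
denominators. Fisher's exact test is two-sided by point-probability
summation (scipy); q-values are Benjamini–Hochberg (statsmodels). Genes
with a zero percentage in either group carry a ±inf sentinel log ratio and
a flag. Note that BH is *not* an idempotent operator (re-adjusting
q-values inflates them); the tested invariants are monotonicity in sorted
p and q ≥ p.

The Wilcoxon rank-sum comparison uses exact enumeration for tie-free
samples with n ≤ 12 and the normal approximation with midrank tie
correction otherwise. Median splits send ties at the median to the low
group (deterministic and testable; an all-equal input degenerates to an
empty high group with a logged warning).

Kaplan–Meier curves are the product-limit estimator computed directly
(equal to the empirical survival function under no censoring,
property-tested, and cross-checked against lifelines). The log-rank test
accumulates observed and expected events over the pooled event times;
chi² = (O_A − E_A)²/V with the usual hypergeometric variance, and the
hazard ratio is the Mantel–Haenszel O/E ratio with CI
exp(log HR ± 1.96·√(1/E_A + 1/E_B)). The O/E estimator was chosen over a
proportional-hazards fit because it is the estimator that pairs naturally
with the log-rank statistic and needs no iterative fitting; it is mildly
conservative (biased toward 1) relative to a Cox fit, visible in the
examples as recovered HR ≈ 1.8 for a true HR of 2 at n = 300/group.

## Network and set enrichment

Graph summaries are taken after dropping edges below a confidence
threshold (nodes are kept even if isolated): average degree is 2E/N
rounded half-up to one decimal, local clustering is the standard
triangles/(deg choose 2) with 0 for degree < 2. Hubs sort by degree then
alphabetically. Set enrichment is the hypergeometric upper tail against a
fixed background, BH-corrected across sets, with strength =
log₁₀(observed/expected overlap); the default retention filter is
p < 10⁻⁵, overlap ≥ 3, strength ≥ 2, each threshold configurable.

Two synthetic network fixtures ship with the package because the
underlying database edge list is not public — and because the published
summary constraints are jointly infeasible for a single simple graph: with
26 nodes and 176 edges the degree sum is 352, but keeping 23/14/13 as the
three largest degrees caps the remaining 23 nodes at 13 × 23 = 299 < 302.
`ppi_fixture()` therefore honors the node/edge counts (average degree
13.5) and `ppi_hub_fixture()` honors the exact hub top-3 (172 edges); both
are deterministic Havel–Hakimi realizations labeled synthetic.

## Synthetic data: what it emulates and what it does not

One root seed fans out to fixed per-generator child streams
(`default_rng([seed, offset])`), so generators are individually and
jointly reproducible. Defaults encode the study conditions:

- **Plates**: five 10-fold doses spanning 0.01–100 µM. The nominal dose
  list of such screens is often quoted with a 0 µM anchor, which cannot
  sit on a log grid; the five *test* concentrations are taken as
  0.01–100 µM. Growth curves are logistic (Hill) in log concentration,
  running from 100% to a floor drawn in [0, 40] (or [−100, −60] for the
  lethal fraction, default 0.3), slopes in [0.5, 3], noise sd 3 PG points
  — a plausible mid-range for SRB screens. Truth tables carry the analytic
  crossings.
- **Fingerprint libraries**: 50-line potency vectors ~N(5.5, 0.8) on the
  −log₁₀ M scale (≈ 3 µM median potency), planted similars built as
  seed + noise with linearly growing sd (a graded similarity ladder), 5%
  missing cells.
- **Alteration cohorts**: ten-thousand-sample scale, 7% index-gene rate,
  per-gene Bernoulli calls with odds multiplied by planted odds ratios
  within index-altered samples.
- **Survival**: exponential event times (baseline 0.03 events/month ≈ 23
  months median survival, matching advanced-cancer cohorts), independent
  exponential censoring, multiplicative group hazard.
- **Predictors**: true targets draw base activity 0.6–0.95 and decoys
  0.05–0.4 before per-predictor noise and optional random dropouts, mapped
  onto each predictor's native score type.

What the generators do **not** emulate: real cell-line identities and
panel-specific sensitivity structure, copy-number vs. mutation subtypes
(alterations are binary), correlated gene–gene backgrounds beyond the
planted index effects, non-proportional hazards, and predictor-specific
biases. Passing recovery tests therefore demonstrates the *statistical
machinery* is correct and calibrated under the stated conditions, not that
it would be similarly powered on any particular real cohort.

## Problem sizes and numerical choices

The test suite runs the calibration checks at sizes chosen to make the
assertions sharp but quick: 200 plates for endpoint recovery (median
|Δlog₁₀ GI50| < 0.15), a 100-compound library for rank recovery, exhaustive
2×2 enumeration for Fisher at margins ≤ 12, 1,000 null simulations at
n = 60/group for log-rank type-I error (accepted band 0.03–0.07 at
α = 0.05), and n = 30,000 with base rates 0.08–0.20 for the null
log-ratio calibration — conditions under which the null sampling sd of the
log₂ ratio stays below ~0.11, so the 0.3 bound sits beyond 2.7σ per gene.
Ties, degenerate inputs, and censoring conventions are each pinned by a
dedicated test rather than left to library defaults.

## Known limitations

- Benzenoid-only aromaticity; no stereochemistry, tautomers, salts or
  SMILES input.
- The TPSA table covers the common neutral/charged N and O environments;
  exotic environments raise by design.
- The O/E hazard ratio is conservative relative to a Cox fit.
- p-values of the co-occurrence table depend on the (unpublished) group
  denominators of real cohorts; only the percentage-derived log ratios are
  reproducible exactly from printed tables.
- COMPARE correlations against the real reference library require that
  library; the module reproduces the algorithm, not the database.
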