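# Methods

## The linkage model

foodsift treats food-database harmonization as record linkage with
blocking: a branded product (query side) is compared only against
reference foods that share its blocking group, a manually assigned
food-classification label that bridges the two databases' otherwise
incompatible category systems. Within a block, candidates are screened by
nutrient-profile distance and name similarity, and survivors are ranked —
never auto-selected: the toolkit's output is a shortlist for a dietetics
expert, and the adjudication module only keeps the books on what the
experts decided.

Both tables must be expressed on a common reference mass (per 100 g or per
100 mL); the toolkit never rescales. Missing nutrient values are tracked
explicitly (`None`), never coerced to zero, and a record fails any filter
that needs a missing field — silently passing incomplete records would
inflate the suggestion lists.

### Nutrient distance

Nutrient distances are differences in each nutrient **as a proportion of
calories**. Absolute gram differences penalize calorie-dense foods;
relative gram differences explode for low-content foods; normalizing each
nutrient's energy contribution by total energy is robust across both ends
of the caloric range, and is invariant under a common rescaling of every
mass-based field of both profiles (a property the test suite checks).

Grams are converted to energy with configurable kcal-per-gram factors
(`energy_factors`): carbohydrate 4, protein 4, total fat 9, saturated fat
9, sugar 4 (as a carbohydrate), fiber 2 (partially fermentable). These are
Atwater-style general factors; any alternative convention can be supplied,
and all reported differences scale accordingly.

Sodium contributes no calories and is compared by relative difference,
normalized by the *product's* sodium content, and only when that content
is non-zero — a zero-sodium product skips the sodium filter entirely
rather than dividing by zero.

Differences are taken as absolute values throughout. The filter
definitions could be read as signed, but a signed comparison would accept
arbitrarily poor candidates on one side of the product, which is never the
intent of a symmetric "how far apart are these foods" screen.

### Filters and comparisons

The five-filter cascade runs in a fixed order (block → macro → secondary →
sodium → fuzzy floor → fuzzy optimization). The first four filters commute
as set operations; fuzzy optimization depends on the surviving pool, so
the order is normative. Two comparison conventions, both switchable on
`SiftParameters`:

* nutrient thresholds are **strict** (`d < t`): a difference exactly at
  the threshold is rejected;
* the minimum fuzzy score is **meets-or-exceeds** (`score >= floor`), so
  the shipped floor of 50 admits a score of exactly 50.

The infinite threshold (spelled `inf` in YAML) disables a filter
completely, including its missing-field requirement.

### Name similarity

The partial token sort ratio is implemented from its definition rather
than delegated to a fuzzy-matching library: normalization (lowercase,
non-alphanumerics to spaces, whitespace collapsed), lexicographic token
sort in plain byte order, then exhaustive enumeration of every
shorter-length window of the longer token string, scoring each window with
the Ratcliff/Obershelp matching-blocks ratio (`100·2M/(|a|+|b|)`, rounded
half-up) and keeping the best. Exhaustive enumeration is the normative
definition here; anchor heuristics found in mainstream libraries vary
across versions, and food names are short enough that exactness costs
nothing. One numerical subtlety: the greedy earliest-longest-block
decomposition is not symmetric in its arguments under ties, so `M` is
defined as the larger of the two argument orders, which makes the score a
well-defined, symmetric function of the string pair. Degenerate inputs are
total: two empty strings score 100, one empty string scores 0. An
independently coded brute-force oracle (explicit recursion, explicit
window enumeration) pins these semantics in the test suite.

### Ranking

For expert review, each candidate's **maximal nutritional difference** is
the largest entry of its difference vector on a common percent scale: the
six caloric differences are already percentage points, and the sodium
relative difference enters as fraction × 100. This mixes two kinds of
percent — a deliberate, literal reading of "the largest of these
nutritional differences" — and `max_nutritional_difference(...,
include_sodium=False)` is provided for users who prefer to rank on the
caloric nutrients alone. Candidates whose difference vector cannot be
computed at all (a reference food with no positive energy, reachable only
under infinite thresholds) rank last with an infinite score. Ties are
broken by food id, ascending, so ranking is deterministic.

## Scheduling

The default schedule mirrors the four-preset protocol: `first` (20/10/0.5)
for everyone; zero-match products fall through `second` (40/40/0.5) and
then `third` (all ∞, fuzzy optimization only); single-match products of
`first` re-run through `first_plus` (60/60/0.5, fuzzy floor 50, no
optimization), whose output **replaces** the original suggestion even when
empty. Replacement is the point: a lone candidate that passed on nutrients
but has a weak name match is considered less trustworthy than no candidate
at all, and is returned to the manual route. An optional
`augmentation_mode: retain_fallback` keeps the original single match when
the augmentation output is empty, for users who prefer recall over that
caution. Single-match products of chain sifts are final — augmentation
applies only to the initial sift's singles. Products ineligible for the
algorithm (zero energy, since energy is the denominator of every caloric
proportion, or a missing field required by some sift in the schedule) are
routed directly to manual matching.

Every sift's bookkeeping satisfies conservation (entered = out₀ + out₁ +
out_many) and the final levels plus the direct-to-manual route partition
the products exactly once; both identities are asserted on every pipeline
test run.

## Agreement and accuracy statistics

Inter-rater agreement is plain percent agreement between exactly two
round-0 raters, as is conventional for this kind of adjudication workflow:

* *selection agreement* — identical verdicts (same food, or both refusing
  all suggestions);
* *manual-needed agreement* — agreement on the refuse-vs-select dichotomy.

Identical verdicts imply dichotomy agreement, so the second rate dominates
the first on any decision log — a structural inequality the property
suite verifies. Cohen's kappa is available as a clearly separate extra
for readers who want a chance-corrected figure. Report tables round rates
half-up to one decimal place. Algorithm accuracy is the fraction of
products with at least one suggestion whose adjudicated match came from
the suggestions, split by match level (single vs multiple) and by a
user-supplied subcategory → reporting-category rollup (an example mapping
ships in `src/foodsift/data/example_rollup.csv`); process accuracy is the
fraction of all products that ended matched rather than unmatchable.

The threshold-sweep diagnostic reruns the three nutrient filters (fuzzy
matching off) over a grid of one threshold and summarizes the 0/25/50/75/
100th percentiles of √(match count) per product — square roots because
counts under loose thresholds span orders of magnitude. Per-product counts
are non-decreasing along the grid, a direct consequence of filter
monotonicity.

## Synthetic data

The generator emulates the *structure* of a branded-product linkage:
category-structured nutrient profiles per 100 g (per-group mean vectors,
log-normal food-to-food scatter), products cloned from reference foods
with bounded multiplicative nutrient noise, marketing-style names (the
source food's tokens shuffled/dropped/inserted plus a brand token), a
fraction of products with no true counterpart, and small fractions of
zero-energy and missing-field products that must be screened out. Defaults
(12 groups, ~8 foods and ~4 products per group, 5% nutrient noise, 20%
token drop/insert, 10% unmatchable, 3% + 3% screening fractions) are a
desk-scale analogue of a national exercise — large enough for stable
counts, small enough that the full suite runs in seconds.

Two choices make recovery provable rather than plausible:

* energy is always recomputed from the caloric nutrients via the energy
  factors, so proportions of calories sum to exactly 100; with each
  nutrient scaled by an independent uniform factor in `[1−a, 1+a]`, a
  clone's proportion-of-calories deviation from its source is at most
  `100·2a/(1−a)` pp. At `a = 0.02` the bound is 4.1 pp — strictly inside
  the 10 pp secondary threshold — so with fuzzy filters off the true food
  *must* survive, and suggestion recall is exactly 1.0, not approximately.
* brand tokens sort lexicographically after every food-vocabulary token,
  so an uncorrupted clone's token-sorted name contains its source food's
  sorted tokens as a contiguous prefix and scores exactly 100; exact
  clones therefore ride through the full default schedule, including the
  fuzzy-floor augmentation sift, with recall 1.0.

What the generator does **not** emulate: real food vocabulary or brand
semantics, heterogeneous subcategories that straddle blocking groups,
label rounding, correlated nutrient errors between databases, or rater
behavior. Passing recovery tests therefore demonstrates the machinery's
correctness under the stated noise model, not field accuracy on any real
database pair.

## Problem sizes and numerical conventions

* Test and acceptance runs use instances of ≤ 20 foods for brute-force
  oracle equivalence (1000 random instances), 500-case property sweeps,
  and generator datasets of a few hundred products (20 groups × ~8
  products for the acceptance script); the whole suite runs in well under
  a minute on one CPU.
* All report rounding is half-up (`floor(x·10 + 0.5)/10` for one decimal;
  likewise for integer fuzzy scores).
* Numeric parsing of input tables is locale-independent: period decimal
  separator, thousands separators rejected, empty/NA cells mapped to
  missing.
* Determinism: the pipeline contains no randomness; the generator uses a
  seeded NumPy PCG64 stream and is byte-reproducible for a fixed seed.

## Known limitations

* Candidates outside the product's blocking group are invisible, however
  close nutritionally — blocking trades recall for focus, and
  heterogeneous product categories suffer most. `blocking=False` exists
  but removes the guardrail entirely rather than softening it.
* The kcal-per-gram factors behind "proportion of calories" are a
  convention; results shift slightly under alternative factor sets, which
  is why they are configurable and recorded in every effective config.
* The maximal-difference ranking mixes percentage-point and relative
  percent scales when sodium is included (see above).
* Only energy plus seven nutrients enter the comparison; two foods can be
  micronutrient-incompatible yet match perfectly here.
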