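# Methods

## Problem and scope

`searchcode` analyzes event logs from a two-arm study design in which
clinicians answered clinical scenario questions with one of two search
engine interfaces: a *resource-based* system (the pre-query profile picks
one of 6 information resources, e.g. PubMed or the Merck Manual) and a
*task-based* system (the profile picks one of 6 clinical tasks, e.g.
diagnosis or treatment).  Both systems accept free-text keywords under
four categories — disease, drug, symptom, other.  The unit of analysis is
the *transition*: an ordered pair of consecutive searches within one
session (one participant, one scenario question).  A log with S sessions
and N searches therefore contains N − S codable transitions per arm.

The scientific question is whether interface design shapes search
behavior: "breadth-first" behavior (trying new profiles while holding the
query fixed) versus "depth-first" behavior (holding the profile while
reformulating the query).

## Coding model

Each transition is coded on two independent axes.

**Profile code.**  Relative to the session's profile history:
`same` (equals the immediately preceding profile), `previous` (used
earlier in the session but not immediately preceding), `new` (first use
in the session).  The three codes partition all cases; `previous` is
structurally impossible at a session's first transition.  History is
session-scoped, and profile comparison is exact string equality after
whitespace trimming, because profiles are menu selections rather than
typed text.

**Query code.**  `none`, `syntactic_only`, `semantic_only`, or
`syntactic_and_semantic`, with syntactic changes subclassified as
capitalization, word order, conjunction (AND/OR/NOT), spacing/grouping
punctuation, or typographic variation (stems, plurals, spellings).
Classification operates per keyword category and ORs flags across the
four categories, so a keyword moved between categories codes as a
semantic remove + add.

The coder runs a fixed normalization cascade — record grouping
punctuation → tokenize → remove conjunctions → case-fold → collapse
typographic variants — so that each syntactic subtype is the change
visible at exactly its own layer.  For combined edits the classifier
pairs words across the two queries: first by equal stemmed base form (in
occurrence order, respecting multiplicity), then by the variant relation
among the remainder.  Paired words differing only in case fire
capitalization; paired variants fire typographic; a changed relative
order of the paired words fires word order; equal character streams with
different word-boundary/grouping structure fire spacing; unpairable
words are semantic additions/removals.  The strict single-edit
`detect_*` predicates and the pairing classifier agree on single edits;
the pairing form exists so that, e.g., a case flip plus an added keyword
codes as capitalization *and* semantic rather than semantic alone.

**Action category and position.**  The profile/query axes collapse to a
4-way action (no change / query only / profile only / both).  Within a
session the first transition is `first`, the final one `last` (when at
least two exist), the rest `middle`; a single-transition session is
`first`.  This labeling is the only one consistent with the published
marginals it is checked against (first-position counts equal the number
of sessions with ≥ 1 transition).  Adjacent transition pairs give the
consecutive-action table; each session's final transition contributes no
pair (the next action was to stop searching), so pairs = transitions −
sessions-with-≥1-transition.

## Typographic-variant relation

The original coding's stemming/spelling rule is not recoverable, so the
variant relation is a declared, configurable stand-in: two case-folded
words are variants iff (a) they share a stem under a light
suffix-stripping stemmer (plural -s/-es/-ies, -ing, -ed with
consonant undoubling), or (b) both have ≥ 4 characters, share their
first 3, and are within Levenshtein distance 2.  Branch (a) covers
apple/apples and run/running; branch (b) covers behaviour/behavior while
keeping short-word false positives rare.  All three thresholds and the
conjunction and punctuation vocabularies are `CoderConfig` parameters.
The distance bound is computed by a small bounded dynamic program; the
stemmer is intentionally conservative and only needs to identify
inflectional variants, not lemmas.

## Statistics

* **Pearson chi-square** of independence on each table, expected counts
  row total × column total / grand total, no continuity correction, df =
  (r−1)(c−1), asymptotic p-value.  Defined only when every margin is
  positive.
* **Wilson score interval** for every cell proportion (count over column
  total), center (p + z²/2n)/(1 + z²/n), half-width
  z·sqrt(p(1−p)/n + z²/4n²)/(1 + z²/n), z = Φ⁻¹(0.975) ≈ 1.959964 at the
  default 95% level.  Bounds are clamped to [0, 100]% against
  floating-point round-off.  The Wilson (not Wald) form is used because
  it is the interval the reference tables for this design print; this
  was confirmed against those tables before the rest of the module was
  built (e.g. 557/1398 → 37.31–42.43, which Wald does not give).
* **Unpooled two-proportion z-test** per row, SE =
  sqrt(p₁(1−p₁)/n₁ + p₂(1−p₂)/n₂), two-sided p.  The unpooled form
  likewise reproduces the reference values (67/1398 vs 74/585 → −5.28,
  where the pooled form gives ≈ −6.2).  Undefined when both proportions
  are 0 or both 1.
* No multiple-testing correction is applied, matching the original
  analysis; the report states how many tests it ran.  Rounding happens
  only at render time: percentages 1 dp, CI bounds and z 2 dp,
  chi-square 2 dp, p as "<.001" below 0.001 and 3 decimals otherwise.

## Synthetic data

**Behavioral sampler.**  A `BehaviorSpec` holds a probability vector
over the 12 (profile code × reformulation type) combinations, a
session-length law, and the vocabularies.  Sessions draw their length
(shifted geometric on {1, 2, …} or fixed), start from a random profile
and keywords, then repeatedly sample an action combination and *realize*
it.  Mass on history-infeasible actions (`previous` before two distinct
profiles exist, `new` after all 6 profiles are used) is redistributed
proportionally over the feasible ones.  Because of this renormalization,
raw empirical frequencies are biased away from the spec vector near
session starts; recovery tests therefore condition on the fully feasible
transitions, where the sampled distribution is exactly the spec vector.
Each session uses its own PRNG substream seeded with (seed, session
ordinal), so output is reproducible and independent of generation order.

The preset specs (`breadth_first_spec`, `depth_first_spec`) default to
the published study's conditions: 39×8 resource-arm and 36×8 task-arm
sessions, mean session lengths 1708/310 ≈ 5.5 and 873/288 ≈ 3.0, and
action probabilities equal to the published per-arm combination
frequencies.

**Edit realization.**  `realize_query_edit` produces keyword maps whose
classification is *exactly* the requested code: syntactic edits are
applied to the disease field (which always carries two distinct-stem
tokens), semantic edits to the drug/symptom fields, so combined targets
decompose cleanly across categories.  Every realization is verified
through the classifier before being returned; infeasible requests (e.g.
word order on a single token) raise and are resampled.  The shipped
keyword vocabulary (~48 clinical-flavored tokens) is screened pairwise
against the variant relation at validation time, so a semantic
replacement can never be mistaken for a typographic variant.

**Exact-fixture builder.**  `fixture_from_counts` deterministically
assembles a log whose coded 12-cell combination table and
position-by-action table equal a target spec cell-for-cell.  Session
layout follows from the position marginals: first − last sessions with
exactly one transition, last sessions with ≥ 2 (middle transitions dealt
round-robin), and the remaining sessions with a single search.  Items
are dealt from per-position pools with three scheduling rules: `previous`
items are drained as soon as a session can host them, a `new` item is
placed early while undrained `previous` items still need future hosts,
and otherwise profile-code classes are balanced largest-first (subject
to the 6-profile cap).  The built log is recoded and compared with the
target before being returned.  `STUDY_FIXTURES` carries the published
per-arm counts; only the combination and position tables are
constrained — the consecutive-pair table of a fixture is an artifact of
the assembly order, since the underlying joint structure was never
published.

## Known limitations

* The synthetic generator emulates coded behavior, not language: its
  keyword strings are vocabulary tokens under mechanical edits, so
  passing tests show that coding and inference are correct given the
  coding rules, not that the rules match any particular human coder on
  messy real queries (misspellings beyond distance 2, synonyms,
  multi-word phrases split across categories).
* The variant relation is heuristic; e.g. change/changing stem to
  different forms under the light stemmer and exceed the distance bound,
  so that pair would code as semantic.  Thresholds are configurable.
* Single-arm logs produce tables without between-arm tests.
* The fixture builder requires target tables that are jointly
  consistent (validated up front); it makes no attempt to match
  pair-table structure.

## Problem sizes

The test suite and the acceptance script run entirely on desk-scale
inputs: the two fixture arms (2581 searches total), sampled logs of a
few thousand transitions for the recovery properties, and 100–1000
random draws for the numerical oracles.  The full suite runs in a few
seconds on one CPU.
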