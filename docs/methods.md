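# Methods

This note documents the models, defaults and numerical choices behind
`fuzzydx`, and what the synthetic evaluation does and does not show.

## Inference model

The engine is a standard Mamdani system: min t-norm for conjunction and
implication (clipping), max t-conorm for aggregation, centre-of-gravity
(COG) defuzzification. Product implication was deliberately rejected:
clipping keeps every intermediate quantity interpretable as "the degree to
which this rule's conclusion is supported", which is the point of a
rule-based clinical tool.

Membership functions are exact piecewise-linear triangles and trapezoids
plus singletons for ordinals. Evaluation is total on the reals (0 outside
the support); a singleton matches within an absolute tolerance of 1e-9.
Crisp inputs outside a variable's domain are clamped to the nearest bound
with a warning rather than rejected — clinical values can exceed nominal
ranges, and clamping preserves the monotone semantics of the extreme
labels. NaN/inf inputs raise and are treated upstream as missing.

### Default partitions

All shipped graded partitions are Ruspini partitions: a left-shoulder
trapezoid, interior triangles, and a right-shoulder trapezoid whose edges
coincide, so membership degrees sum to 1 everywhere in the domain. This
makes fuzzification degrees read as proportions and makes the partition
sum a machine-checkable invariant (asserted to 1e-9 in the tests).
Published partition diagrams for these instruments are qualitative, so the
breakpoints are our own clinically-plausible design values, shipped as
data (`data/partitions.json`) and fully user-overridable. Two anchors are
fixed by design:

- **ADAS13** (five terms on [0, 85], the instrument's full clinical
  range): the VeryLow/Low crossover is placed so that a score of 9
  fuzzifies to VeryLow 0.75 / Low 0.25, the canonical worked example for
  this kind of system.
- **CDRSB** (four terms on [0, 18]): trapezoid–triangle–triangle–trapezoid,
  matching the usual VeryLow/Low/Medium/High reading of the instrument.

The output variable `DR` spans [0, 100] with peaks at 10/30/50/70/90 for
CN/SMC/EMCI/LMCI/AD. The edge classes are shoulder trapezoids rather than
clipped triangles so that the output partition is itself Ruspini over the
whole domain; the interior classes are symmetric triangles, which makes
`classify` unambiguous (crossovers at 20/40/60/80, ties broken toward the
less severe class).

### Defuzzification

COG is computed by trapezoidal integration of the clipped-max envelope on
a uniform grid, default 1001 points (sub-0.1% grid error at negligible
cost; doubling the resolution moves DV by < 1e-3 of the domain width on
the shipped output sets). The engine is cross-checked in the tests against
an independently coded literal min/max/COG oracle (1e-6 at equal
resolution) and against a 10^6-point integration oracle (1e-4 of the
domain width, engine run at a converged 2×10^5-point grid since randomly
generated test sets can be much narrower than the shipped ones).

## Rulebase

The rule dialect is a minimal FCL-style text format — `RULE id: IF v IS q
(AND v IS q)* THEN DR IS class;` — with case-insensitive keywords and
alias-aware variable resolution. Only conjunctions are supported; the
shipped rules are pure conjunctions and a richer grammar would buy nothing
but ambiguity.

**Missing features skip the whole rule.** When any antecedent variable is
absent from the record the rule contributes 0 and is marked
`skipped-missing` in the trace. The alternative (dropping the missing atom
and evaluating the rest) silently weakens a rule's clinical meaning;
whole-rule skipping keeps each rule's semantics intact and lets coverage
under missingness come from rulebase redundancy, which the shipped
rulebase provides (every class is covered by several rules over different
feature subsets).

The shipped rulebase has two layers: an 18-rule core (7 CN, 2 SMC, 4 EMCI,
2 LMCI, 3 AD; every rule carries both severity atoms) and 7 documented
extensions (`rules_extended.fcl`) adding biomarker patterns the core
leaves uncovered — FDG hypometabolism with hippocampal/medial-temporal
atrophy for EMCI, and the amnestic high-ADAS13 / high-forgetting /
elevated-tau profile for LMCI. The layers live in separate files so the
core can be tested in isolation. "Dynamic" behaviour comes entirely from
routing open-vocabulary text into the `S_Severity`/`C_Severity` atoms at
runtime; no rules are rewritten or learned at runtime.

## Semantic severity

Concepts live in a rooted is-a hierarchy (one root per category, symptom
and complication), validated at load time for cycles, orphans and
duplicate ids. `part-of` relations are loaded as annotations but ignored
by similarity — no well-defined similarity semantics exists for them here.

Term matching normalizes text (lowercase, punctuation stripped, whitespace
collapsed) and tries, in order: exact preferred-label match, exact synonym
match (both similarity 1.0), then fuzzy lexical matching over all
labels/synonyms with a 0.85 normalized string-similarity gate
(difflib ratio). A fuzzy candidate's final similarity is its string
similarity times the Wu–Palmer similarity between the candidate and its
best structural anchor in the is-a neighborhood; on tree-shaped
taxonomies the anchor is the candidate itself, so the factor is 1 — the
hook matters only for DAG taxonomies where a lexical hit may sit under
multiple parents. Anything below the floor τ = 0.5 is unmatched, which is
a value, not an error. Both thresholds are exposed in config; they are
conservative defaults, not fitted quantities.

Wu–Palmer was chosen because the structural neighborhood it encodes —
parent and siblings — is exactly the neighborhood that makes near-synonym
symptom terms interchangeable in this setting. Depth counts from 1 at the
category root; multi-parent nodes use the shortest root path and the
deepest common subsumer.

Severity aggregation is the similarity-weighted mean of matched concepts'
0–10 severity weights (bounded by the min/max contributing severity); a
`max` aggregator (max of sim·sev, monotone in both) is selectable for
screening-style use. Scores aggregate over **all** matched terms of a
category, not only rule-relevant ones — the alternative would make a
term's influence depend on which rules exist, breaking the separation
between knowledge base and patient data. Manual per-term severity
overrides (the clinician's judgement) take precedence over taxonomy
weights and apply within the list the term was reported in.

## Synthetic cohorts

The generator exists so the whole pipeline is testable without
registration-gated clinical data. Each class has a prototype
(`data/prototypes.json`): truncated-normal location/spread per feature
(truncation respects the schema domain, avoiding clamping artifacts) and
symptom/complication pools with draw probabilities. The prototypes encode
the qualitative class structure of real baseline cohorts — high FAQ/CDRSB
with severe symptoms for AD; high MMSE/MoCA with benign symptoms for CN;
elevated LDELTOTAL, percent forgetting, ADAS13, ventricles and CSF tau for
LMCI; low FDG, MidTemp and hippocampal volume for EMCI; near-normal
numerics with low-grade memory-concern symptoms for SMC. Every subject
draws at least two symptoms and one complication so the semantic stage
always has input. Draws use a single integer-seeded generator; identical
specs produce identical cohorts.

What passing the synthetic recovery check (≥ 95% class recovery at 100
subjects/class) shows: the partitions, rulebase, taxonomy and severity
scoring are mutually consistent end to end, including under feature
missingness. What it does not show: performance on real patients. The
prototypes are well-separated design values with no covariance structure,
no label noise, no atypical presentations, and a closed symptom
vocabulary; real cohort accuracy claims require real cohorts.

Fixture severity weights follow a simple convention: benign somatic terms
1–3, mood/sleep terms 3–5, cognitive-functional decline 7–8, severe
complications 7–9. One fixture naming note: generic leaves such as "light
sweating" sit under a general-symptom branch purely to keep the fixture
compact.

## Degenerate inputs and tie-breaks

- No rule fired → `EmptyOutput` internally, surfaced as an INCONCLUSIVE
  diagnosis (exit status 0): clinically safer than forcing a nearest
  class, and it makes rulebase coverage gaps visible.
- `classify` ties (DV exactly at a crossover) break toward the less
  severe class.
- Empty symptom/complication lists give severity 0, which fully satisfies
  the `Low` severity label — absence of reported symptoms is evidence of
  mildness, not missingness (the lists are always observed, possibly
  empty; numeric features are the ones that can be missing).
- Records whose every feature is unknown to the partition registry simply
  fuzzify nothing and come out INCONCLUSIVE.

## Known limitations

- Breakpoints, severity weights and prototypes are design values, not
  fitted to any dataset; the package is a framework plus a defensible
  default configuration, not a validated diagnostic instrument.
- Only conjunctive rules; no hedges, no type-2 sets, no Sugeno inference.
- Wu–Palmer on shallow fixtures is coarse: all sibling pairs at one depth
  share the same similarity.
- Severity aggregation treats matched terms as independent; repeated
  near-synonyms inflate neither the mean (good) nor the evidence count
  (a duplicate-aware weighting is future work).
- One row = one subject at baseline; longitudinal trajectories are out of
  scope.
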