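# fuzzydx

Interpretable, rule-based staging support for Alzheimer's disease and its
prodromal stages. `fuzzydx` implements a Mamdani fuzzy-inference engine
whose diagnostic rules combine ordinary clinical measurements (cognitive
scores, CSF markers, MRI volumetrics, FDG-PET) with two inputs that are
computed at runtime by semantic reasoning over a clinical taxonomy: the
severity of the patient's reported **symptoms** (`S_Severity`) and
**complications** (`C_Severity`). Because free-text terms are resolved
through synonyms and taxonomy structure rather than literal string
comparison, a rule written against "confusion" still fires for a patient
described as *anxious*, *suspicious* or *fearful* — the rulebase is
dynamic with respect to open symptom vocabulary while every decision
remains fully explainable.

## The model

Each input feature is a linguistic variable `V_j = (v_j, X_j, Q_j, S_j, I_j)`:
a name, a closed numeric domain, an ordered label set (e.g. VeryLow …
VeryHigh), and one fuzzy set per label. Shipped partitions are Ruspini
partitions (degrees sum to 1 everywhere) built from triangular and
trapezoidal sets; APOE4 allele count is a nonfuzzy ordinal modelled with
singletons. Inference is classical min–max Mamdani:

- **Fuzzification** — a crisp input `x0` yields degrees `μ_k(x0)` in every
  set of its variable.
- **Rules** — pure conjunctions `IF v1 IS q1 AND … THEN DR IS class`;
  firing strength is the min over atom degrees. A rule referencing any
  feature missing from the record is skipped (strength 0) — tolerance to
  null values comes from rulebase redundancy, never from imputation.
- **Aggregation / implication** — consequent sets are clipped at the firing
  strength (min implication) and combined with max.
- **Defuzzification** — the diagnosis value `DV(p)` is the centre of
  gravity of the aggregated output set on a uniform grid; the output
  partition over [0, 100] maps `DV(p)` to CN, SMC, EMCI, LMCI or AD (ties
  break toward the less severe class).

Symptom severity is computed by matching each reported term to a taxonomy
concept (exact label → synonym → fuzzy lexical matching), weighting the
concept's 0–10 severity by the match similarity, and averaging:
`S = Σ sim_i · sev_i / Σ sim_i`. Concept relatedness uses Wu–Palmer
similarity `2·depth(LCS) / (depth(a) + depth(b))` on the is-a hierarchy.

## Worked example

Generate a small labelled synthetic cohort, diagnose it, and inspect one
patient's trace:

```sh
$ fuzzydx simulate -o demo.csv --n-per-class 2,2,2,2,2 --seed 7
wrote 10 records -> demo.csv
$ fuzzydx diagnose demo.csv -o demo_results.csv
diagnosed 10 records (0 inconclusive) -> demo_results.csv
$ head -3 demo_results.csv
RID,DV,predicted,act_CN,act_SMC,act_EMCI,act_LMCI,act_AD,n_rules_fired
1,19.423584,CN,0.835189,0.454710,0.000000,0.000000,0.000000,8
2,18.824153,CN,0.975212,0.476257,0.000000,0.000000,0.000000,6
$ fuzzydx explain demo.csv 5
Patient 5
  Symptom matches:
    'anxious' -> anxiety [route=synonym, sim=1.000]
    'fearful' -> fear [route=synonym, sim=1.000]
    'suspicious' -> suspicion [route=synonym, sim=1.000]
  Complication matches:
    'arterial hypertension' -> arterial-hypertension [route=exact-label, sim=1.000]
  S_Severity = 4.000
  C_Severity = 4.000
  Fired rules (4 of 25):
    c10: strength 0.800 -> EMCI
    e4: strength 0.795 -> EMCI
    e3: strength 0.781 -> EMCI
    c7: strength 0.082 -> CN
  DV(p) = 46.097  (grid resolution 1001)
  Diagnosis: EMCI
```

Reading the trace: three mood-branch synonyms resolved to taxonomy
concepts with severity 4, so `S_Severity = 4.0` sits in the *Average*
band; the early-MCI rules (hypometabolism + medial-temporal atrophy, and
the cognitive-screen pattern) fire at ~0.8 while one CN rule barely fires
at 0.08, so the centroid lands at 46.1 inside the EMCI output set. With a
fuzzification like `ADAS13 = 9 → VeryLow 0.75 / Low 0.25`, every number in
the pipeline is auditable by hand.

The same machinery is available as a library — see `fuzzydx.diagnose_record`,
`fuzzydx.match_term`, `fuzzydx.parse_rules` — and all shipped configuration
(partitions, rulebases, feature schema, taxonomy, generator prototypes)
lives in editable JSON/FCL data files under `src/fuzzydx/data/`.

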