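# Methods

## The decision model

`emsafe` separates *fact retrieval* from *clinical judgment*. The judgment is
a typed DAG of concepts (the ontology) with one executable rule per derived
or output node. Evaluating a determination means backward-chaining from the
output node to exactly its ancestor set, then executing those nodes in
topological order. Ties among simultaneously-ready nodes break
lexicographically by node id, so the execution trace for a given chart is
identical across runs and platforms.

The bundled epinephrine ontology has six input nodes (age, weight,
administered dose, EMS-arrival time, arrest-onset time, first-dose time),
four derived nodes (recommended dose, dose ratio, and the two elapsed-time
clocks), and three outputs (overdose, underdose, delay), each a categorical
`none/mild/severe`. Age is extracted and audited but feeds no rule: the
0.01 mg/kg recommendation is weight-based, and indication logic
(failure-to-administer) is out of scope.

Key assumptions:

- **Per-administration dosing, chart-level roll-up.** Overdose/underdose are
  properties of a single administration; a chart's label is the worst
  severity across its administrations (`none < mild < severe`). Gold labels
  in review practice are chart-level, which is what evaluation consumes.
- **Delay AND-semantics.** The delay criterion requires the first dose to
  follow *both* EMS arrival and arrest onset by the threshold, implemented
  as thresholding the minimum of the two elapsed times. This reading follows
  the conjunctive phrasing of the criterion; it is stated here explicitly
  because it is easy to mis-implement as either-clock.
- **Zero doses are non-administrations.** A 0 mg record is excluded from
  underdose classification (it would otherwise conflate underdose with
  failure-to-administer); it still passes through overdose classification,
  where it is trivially `none`.
- **Nested severities.** Severe thresholds lie inside mild ones
  (10 ≥ 2, 0.5 ≤ 0.8, 10 ≥ 5), so severe always implies the mild criterion;
  classification returns the worst satisfied level.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| recommended dose | 0.01 | mg/kg | PALS weight-based dosing for pediatric arrest |
| overdose thresholds | 2 (mild), 10 (severe) | × recommended | guideline criteria |
| underdose thresholds | 0.8 (mild), 0.5 (severe) | fraction of recommended | guideline criteria |
| delay thresholds | 5 (mild), 10 (severe) | minutes, both clocks | guideline criteria |
| boundary tolerance | 1e-9 | relative | a 10× decimal-shift error whose ratio computes as 9.999999999… must classify severe; clinically indistinguishable from the boundary |
| extraction retries | 1 | — | one re-ask on schema-violating backend output, then abstention |
| sandbox probe timeout | 1.0 | s | long enough for any arithmetic rule, short enough to catch hangs |
| delay policy | `strict` | — | refuse to classify delay without an arrest-onset time; `arrival_only` classifies on one clock and flags it in the evidence |

The `strict` default is deliberate: imputing arrest onset would manufacture
a clock the chart does not document. `arrival_only` exists because many real
charts lack a usable arrest time and an arrival-only screen is still
operationally useful; when active, the evidence dictionary says so.

## Extraction and abstention

One extraction call per chart covers all input nodes. The output schema has
one nullable slot per scalar node plus an `administrations` array (drug,
dose, unit, time per row) that realizes the per-administration dose/time
facts; `first_epi_time` is the earliest extracted epinephrine time.

Conflict policy: distinct values for the same fact *after unit
normalization* (mg↔mcg, numeric equality so "1 mg" = "1.0 mg") are a
conflict and produce an abstention with reason `conflicting_values`;
identical duplicate mentions are not. Sources are treated uniformly — a
templated structured-field sentence has no priority over a narrative
sentence, so a structured/narrative disagreement abstains rather than
trusting either entry.

The bundled `MockExtractor` is a deterministic pattern-based backend
(quantity+unit, ISO-timestamp, and drug-dose-time regular expressions over
the numbered sentences embedded in the prompt). It honors the same
stateless prompt+schema contract as an external LLM and is the offline test
surface; it is not a claim about language-model behavior.

## The rule engine and its sandbox

Rules are Python source files defining `rule(<deps>)`, compiled into a
namespace with a stripped builtins table and checked against a static AST
denylist (no imports, no I/O/process/reflection names, no dunder access),
then probed once on placeholder inputs in a forked subprocess under a
timeout. Only explicitly promoted (`verified`) rules execute; the bundled
rules ship pre-verified with sha256 hashes checked at load. This is a
desk-scale safety boundary against accidents and obviously hostile generated
code, **not** OS-level isolation — a determined adversary with write access
to the rule files is outside the threat model (the manifest makes tampering
detectable, not impossible).

Execution encodes all failures as trace entries (`missing_input`,
`coercion_failure`, `rule_error`) with the origin node id; descendants of a
failed node carry the same kind and origin. The target's outcome is either a
typed value or a propagated error — exceptions never escape `execute`.

## What the synthetic cohorts emulate — and what they don't

The generator emulates: pediatric encounters with age-banded weights
(1–14 y, ~9–55 kg; infants under 1 y are not modeled), arrest onset 0–5 min
before EMS arrival, one to two epinephrine administrations whose dose ratios
realize sampled per-category labels with safety margins, facts realized as
structured fields and/or paraphrased narrative sentences, conflicting
duplicate weight (or dose) entries, decimal-shift dose errors, and ±2%
dose-recording jitter. Gold labels are recomputed from the *recorded* facts
using threshold arithmetic written inline in the generator — no code is
shared with the ontology rules or the reference functions, so end-to-end
label recovery is a genuine cross-implementation check.

It does **not** emulate: realistic clinical narrative style (sentences come
from small paraphrase pools), OCR/typo noise, route-dependent dosing,
reviewer disagreement, or charts lacking epinephrine entirely. Passing tests
therefore demonstrate the correctness of the pipeline's mechanics on charts
whose facts are expressible in this dialect — not field performance of any
particular extraction backend on real narratives.

Default noise rates (3% conflicts, 5% decimal shifts, 30% narrative-only
facts, 2% jitter) are of the magnitude reported for documentation problems
in real chart review; several tests and the end-to-end recovery check run
with all noise channels off, which is stated where it applies.

## Numerical and design choices

- Timestamps are ISO-8601, timezone-aware (naive input assumed UTC);
  elapsed times are real-valued minutes.
- Quantities are converted to the node's declared unit before any
  comparison; cross-dimension conversion is an error, not a pass-through.
- The sentence tokenizer is a punctuation-rule splitter with a clinical
  abbreviation exception list ("approx.", "pt.", "i.v.", …); unit tokens
  deliberately do *not* suppress boundaries ("Gave 0.1 mg. Pt improved."
  splits). Decimal points never split (no whitespace follows).
- Evaluation counts a missing or unclassifiable prediction as a negative
  prediction with a logged warning, keeping denominators honest.
- Binary scoring treats mild-or-severe as the positive class by default; a
  severity-stratified mode scores each level separately. F is NA when
  precision or recall is undefined, or both are zero.
- Agreement: AC1 uses `pe = 1/(q-1) · Σ π_k(1-π_k)` with π_k the mean rater
  marginal; the single-category degenerate table returns AC1 = 1 and
  kappa = NA (pe = 1).
- Problem sizes in the checked properties — 500-chart recovery cohorts,
  1,000 random input vectors for engine-vs-reference equivalence, 200 random
  DAGs (≤ 12 nodes) against a brute-force ancestor oracle — were chosen as
  comfortably exhaustive for graphs and classifiers of this size.

## Known limitations

- The bundled ontology reconstructs the epinephrine criteria at a node
  granularity chosen here; other decompositions of the same criteria are
  possible and would yield identical determinations with different traces.
- Whether mild delay should also require both clocks, and whether arrest
  onset may ever be imputed, are policy questions; the defaults (both
  clocks, no imputation) are documented above rather than claimed as the
  only defensible reading.
- The NEMSIS dialect here is a flat JSON/CSV projection of the elements the
  ontology needs; full NEMSIS XML ingestion would be an adapter behind the
  same reader interface.
- No external LLM backend is bundled; robustness of real extraction is
  bounded by the backend supplied, and the abstention/validation layer can
  only refuse bad output, not repair it.
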