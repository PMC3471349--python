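# Methods

## Data model

An **annotation** is one resource's record of an in-situ hybridisation
finding: `(gene, structure, Theiler stage)` plus an expression-level claim
and quality metadata (probe information present/absent/unknown, an optional
curator-confidence ordinal, a provenance URL). The mouse's development is
divided into 28 Theiler stages (27 = newborn, 28 = adult), each with its own
anatomy: a DAG of structures under *part-of*, in the style of the EMAP atlas.
Part-of edges never cross stages and there is no cross-stage propagation.

Level claims are **sets** over the canonical scale
`not_detected < weak < moderate < strong`. Set semantics carries exactly the
information a resource commits to: EMAGE's "detected" and GXD's "present"
assert expression without a strength and map to `{weak, moderate, strong}`;
GENSAT's "moderate to strong signal" maps to `{moderate, strong}`. Absence is
mutually exclusive with any positive level, so `{not_detected}` is always a
singleton. GENSAT's "not done" carries no finding at all (`no_data`) and is
dropped at load time with a logged count. GXD's positive vocabulary is
assumed to mirror EMAGE's apart from the documented absent/present
substitutions; the mapping table is fixed and shipped.

ABA publishes numbers, not terms. Of its three published measures (raw,
per-gene averages, level-times-density aggregate) only the raw value is
consumed — it is the one suited to per-experiment reasoning. Raw values are
categorised by per-structure cut-off rows `(weak_min < moderate_min <
strong_min)`; a structure without a row inherits the nearest ancestor's row
(breadth-first, ties by identifier sort), mirroring how the limits are
propagated down the brain hierarchy. Intervals are lower-inclusive,
upper-exclusive; no convention is published, so one was fixed and is stated
here. No real ABA cut-off values are published either, so none ship: cut-off
tables are user-supplied or fixture-generated (the fixture's row is labelled
synthetic). Foreign anatomies (GENSAT, ABA) map onto EMAP through alignment
tables; a mapping flagged many-to-one, or fanning out to several EMAP terms,
sets a precision-loss flag that is logged as a warning.

## Propagation

Because the anatomy relation is part-of, a positive finding in a structure
holds in every structure it is part of. `propagate` adds, for each *direct
positive* annotation, one derived record per ancestor in the part-of closure,
flagged `propagated` with the source id recorded. Two deliberate
restrictions:

* **Absence never propagates.** Upward lifting of "not detected" is unsound
  (a gene absent in a part may be present elsewhere in the whole) and
  downward lifting, though biologically common, is not implemented — only
  what the part-of semantics licenses is derived. (A config flag for
  absence-down would be a backwards-compatible extension.)
* **Single hop from direct records.** Derived records are never re-derived
  from; since the closure is already transitive this loses nothing, keeps
  provenance one level deep, and makes the operation idempotent.

Ancestor order is breadth-first with lexicographic tie-break, so all outputs
are reproducible.

## Agreement granularity

Whether two annotations (same gene, structure, stage — otherwise they are
*independent*) agree depends on the question. At **presence** granularity,
two positive claims agree whatever their strengths, and absence conflicts
with any positive claim. At **level** granularity, claims agree iff their
level sets intersect — so "detected" is compatible with any positive level —
and conflict otherwise. The relation is symmetric, and level-mode agreement
between positives implies presence-mode agreement. Direct and propagated
records compare identically here; the preference for direct evidence is
applied in the engine and summariser, keeping the relation a pure comparison.

## Schemes and expert reconciliation

Schemes are data files (JSON/YAML): a natural-language statement, conditions
drawn from a closed predicate catalogue (`asserts_expressed`,
`multiple_agreeing_annotations`, `probe_info_absent`,
`origin_is_propagated`, `cross_resource_corroboration`, ...), a conclusion
that supports or attacks one of `expressed(g,s,t)`, `level(g,s,t,L)` or
`trust(annotation)`, and a confidence score on the five-point ordinal scale
`0 (reject) < ? (borderline) < 1 (weak) < 2 (moderate) < 3 (good)`, ranks
0–4. Schemes scored 0 load but never compile into rules; borderline schemes
compile at the lowest usable preference.

When a file carries two experts' scores per scheme, `reconcile` classifies
each pair as *exact* (equal ranks), *adjacent* (ranks differ by one — if one
expert says 2, either 1 or 3 counts as similar) or *disagree*, and reports
the broad-agreement and disagreement percentages rounded half-up to
integers. Whether borderline is adjacent to both reject and weak is not
settled anywhere authoritative; the scale is taken exactly as ordered above,
and the choice is isolated in `classify_agreement`. The combined score
defaults to the **minimum** of the two ranks: expert disagreement over these
schemes was never resolved, so the conservative floor is the honest default
(`max` and `midpoint` are available by argument).

## The argumentation engine

Annotations translate into ground facts (one `asserts` fact per record plus
polarity, per-level, origin, probe and resource flags, and pairwise
agreement/conflict/corroboration facts at the chosen granularity).
Non-rejected schemes compile into defeasible rules that inherit their
scheme's confidence. Forward chaining runs to fixpoint; each distinct
minimal derivation (rule plus specific sub-derivations) yields one argument,
whose confidence is the **weakest link** — the minimum rank among the rules
used, facts counting as axiomatic above all rule ranks. Weakest-link is the
standard conservative aggregation in structured argumentation; nothing finer
is warranted when the only per-rule information is an ordinal. Derivations
where a conclusion would feed its own support are skipped, and termination
is guaranteed (function-free rules, finitely many constants). A configurable
cap (default 1000) aborts construction with an explicit error: well-studied
queries can otherwise yield hundreds of arguments no reader will scan.

Two arguments **rebut** when their conclusions are complementary; in level
mode, distinct positive level claims for the same key also rebut. Defeat is
preference-based: attacker defeats target iff its confidence is ≥ the
target's. The ≥ (rather than >) matters: with strict preference two
equal-confidence rebuttals would both stand, silently presenting
contradictory conclusions as jointly valid; with ≥ they defeat each other
and the grounded labelling marks both *undecided*, which the summariser
surfaces as unresolved conflict. One exception overrides confidence
entirely: a **direct-origin argument defeats a propagated-origin rebuttal
outright, and the propagated side gets no edge back** — biologists prefer
direct annotations, so a direct "not detected" on the future brain overrides
a weak-expression claim lifted there from the telencephalon regardless of
ranks. Suppressing the reverse edge is what makes the direct record *take
precedence*; keeping it would drag both into undecided whenever the
propagated side's confidence is equal or higher.

Statuses are the **grounded** (sceptical, unique) labelling: IN when every
attacker is OUT, OUT when some attacker is IN, UNDEC otherwise. Grounded was
chosen over preferred/stable semantics because it is deterministic, unique,
and matches the intended engine behaviour of a single verdict per argument;
the test suite checks it against an independent defence-fixpoint oracle
(least fixpoint of F(S) = the arguments whose attackers are all attacked
by S).

The engine is optional at query time: the summariser runs directly from
annotations, and the engine backs the `--argue --full` path and the library
API.

## The summariser

The output deliberately contains **no overall conclusion**. Users of systems
that printed "the gene appears to be expressed" disagreed with the verdict
as often as not — the judgement is subjective — so the tables only present
per-conclusion reasons, each cell a tick (reason to trust), cross (reason to
doubt) or dash (datum unavailable) with the justifying annotation ids
attached.

*Per level* (one row per level with ≥ 1 supporter, where a record supports
every level in its set — "detected" supports all three positive rows): the
three attributes are **corroboration** (≥ 2 supporters), **unopposed** (no
conflicting record at the chosen granularity) and **direct support** (≥ 1
non-propagated supporter). Only "multiple annotations agree" is an
attested attribute name; the triple was chosen to cover the three scheme
families that dominate the catalogue — agreement, conflict, propagation —
and is recorded in `LEVEL_ATTRIBUTES` so users can substitute their own.

*Per annotation*: probe information (unknown → dash), direct vs propagated,
cross-resource corroboration (dash when only one resource reports at all),
multiple-annotations-agree, and curator confidence against a threshold
defaulting to the midpoint (3) of the 1–5 ordinal range, dash when absent.
Negative cells cite the records that demonstrate the negative (the
conflicting ids for *unopposed*, the lone supporter for *corroboration*, the
annotation itself for its own flags), so every tick and cross is traceable.

Rendering is ASCII `+ / x / -` by default (`✓ / ✗ / –` behind `--unicode`),
with TSV and JSON (evidence inline) for machines. Logging goes to stderr,
tables to stdout.

## Synthetic fixtures

Real inputs are live databases and an unpublished scheme set, so the
generator reproduces their statistical structure rather than their content.
Defaults are the study conditions the package targets:

| knob | default | rationale |
|---|---|---|
| scheme_counts | (68, 16, 33, 19) | the documented two-expert scoring split |
| ontology stage | 15 | the classic bmp4/future-brain stage |
| focal case | 2 agreeing + 1 conflicting | the canonical strong/strong/not-detected disagreement |
| ontology | 30 nodes, ≤ 2 parents | small staged DAG with the named chain telencephalon → future_brain → embryo |
| n_genes | 5 | background noise without blowing up runtime |
| resource_mix | .4/.4/.1/.1 EMAGE/GXD/GENSAT/ABA | EMAGE and GXD dominate mouse in-situ coverage; the brain atlases are supplementary |
| fraction_propagated | 0.25 | a minority of records derived, as in practice |
| fraction_probe_missing | 0.3 | probe metadata is commonly absent |

Expert score vectors are constructed to realise the requested
exact/adjacent/disagree counts exactly under `classify_agreement` (category
order shuffled, pairs drawn per category; infeasible requests error).
Annotation rows are written in each resource's *own* vocabulary so loading
exercises the full harmonisation path: GENSAT rows can only carry levels its
vocabulary can express, ABA rows are numeric, use foreign structure ids
routed through a generated alignment table (the focal mapping flagged as
precision-losing), and are always direct — re-expressing a derived record as
a raw ABA number would fabricate a measurement. Propagated slots therefore
draw from the term-based resources only. Everything is a pure function of
the spec including the seed: reruns are byte-identical.

What the generator does **not** emulate: real EMAP identifiers and anatomy
depth, realistic per-gene annotation densities, correlated curator
behaviour, image-derived uncertainty, or the content of the 68 real schemes
(only their count distribution). Passing tests therefore demonstrate the
machinery — harmonisation, propagation, defeat semantics, rendering — not
biological conclusions about any real gene.

## Numerical and procedural choices

* Percentages round half-up to integers; agreement categories partition
  exactly (enforced).
* All orderings (ancestors, facts, arguments, table rows) are
  deterministic: breadth-first with lexicographic tie-breaks, or sorted
  (resource, id).
* Edge-TSV ontologies may introduce nodes only seen as parents; ids are
  per-stage and cross-stage edges are rejected. Cycles abort loading with an
  edge on the cycle named; dangling parents are named.
* Problem sizes in the test suite and acceptance script — 500 random defeat
  graphs of ≤ 12 arguments, 200 random DAGs of ≤ 50 nodes, three fixture
  seeds — were chosen to exercise the combinatorics thoroughly while keeping
  a full run in the seconds range.
* Empty query results, empty summaries and zero-argument evaluations are
  valid outcomes, not errors.

## Known limitations

* No gene-symbol synonym resolution (verbatim, case-insensitive comparison).
* No is-a reasoning, ontology editing, or computed alignments; part-of
  transitive closure is the only inference over the anatomy.
* No dialogue protocols, burden of proof, or probabilistic argumentation;
  confidence is ordinal and the only preference source.
* Rebuttal is the only attack form; undercutting (attacking a rule's
  applicability rather than its conclusion) is expressible only indirectly
  via `trust` conclusions.
* The GXD positive vocabulary is an assumption (documented above), and
  whether real EMAP pipelines chain propagation through derived annotations
  is unknown; single-hop-from-direct is this package's contract.
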