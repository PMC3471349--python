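# argudas

Aggregate, harmonise and *argue over* in-situ hybridisation gene-expression
annotations for the developmental mouse.

## The problem

Online resources that republish in-situ experiments — EMAGE, GXD, GENSAT, the
Allen Brain Atlas (ABA) — are individually incomplete and mutually (even
internally) inconsistent: one annotation says a gene is expressed in a
structure, another says it is not detected there. They also disagree about
everything else: GXD says *absent* where EMAGE says *not detected*, GENSAT
uses phrases like *moderate to strong signal*, ABA publishes raw floating
point values, and the brain atlases use their own, finer anatomies than the
EMAP staged mouse anatomy used by EMAGE/GXD.

This package puts all of that onto one footing and then summarises the
evidence for a biologist's query — *is gene g expressed in structure s at
Theiler stage t, and at what level?* — **without deciding the answer**.
Whether a body of partially conflicting evidence adds up to "expressed" is
subjective; the package's job is to lay out, for each candidate conclusion,
the reasons to trust it and the reasons to doubt it.

## What it does

* **Anatomy** (`argudas.ontology`): the 28-stage EMAP-style part-of hierarchy
  (stage 27 = newborn, 28 = adult; each stage has its own anatomy). Positive
  findings are propagated up the part-of closure — weak expression in the
  telencephalon is weak expression in the future brain — while *not detected*
  findings never propagate.
* **Vocabulary** (`argudas.vocabulary`): every resource's level terms map
  onto the canonical scale `not_detected < weak < moderate < strong` as *sets*
  of possible levels ("detected" = {weak, moderate, strong}, "moderate to
  strong signal" = {moderate, strong}); ABA raw values are categorised via
  per-structure cut-off tables inherited down the hierarchy, and foreign
  anatomies map onto EMAP through alignment tables with precision-loss flags.
* **Agreement** (`argudas.annotations`): whether two annotations agree depends
  on the question. At *presence* granularity a strong and a weak finding
  agree; at *level* granularity they conflict. Both modes are first-class.
* **Schemes** (`argudas.schemes`): curatorial know-how ("if several
  annotations agree, trust the finding more") is consumed as data files, each
  scheme scored on the ordinal scale 0 (reject) < ? < 1 < 2 < 3 (good). Two
  experts' score vectors are reconciled into exact / adjacent / disagree
  categories with the conservative minimum as the combined score.
* **Engine** (`argudas.engine`): schemes compile into defeasible rules; facts
  derived from annotations feed forward chaining; each derivation becomes an
  argument whose confidence is its weakest link. Arguments with complementary
  conclusions rebut; the higher confidence defeats, direct annotations take
  precedence over propagated ones outright, and statuses are the unique
  grounded labelling (ties come out *undecided*, not swept under the rug).
* **Summariser** (`argudas.summarizer`): the final presentation is two
  key-attribute tables — per expression level and per annotation — of ticks
  (`+`, a reason to trust), crosses (`x`, a reason to doubt) and dashes
  (`-`, data unavailable), each cell carrying the annotation ids that justify
  it. No overall verdict is ever printed.
* **Fixtures** (`argudas.fixtures`): a deterministic generator for complete
  synthetic bundles (ontology, annotations across all four resources,
  cut-offs, alignments, doubly-scored schemes) emulating the statistical
  structure of the real resources.

## Worked example

```bash
argudas fixtures --out demo --seed 7
argudas query --gene bmp4 --structure future_brain --stage 15 --argue --data demo
```

```
annotation  resource  gene  structure     stage  level         origin  url
----------  --------  ----  ------------  -----  ------------  ------  ----------------------------
GXD:0001    GXD       bmp4  future_brain  15     strong        direct  https://example.org/gxd/0001
GXD:0002    GXD       bmp4  future_brain  15     strong        direct  https://example.org/gxd/0002
GXD:0003    GXD       bmp4  future_brain  15     not_detected  direct  https://example.org/gxd/0003

level         corroboration  unopposed  direct_support
------------  -------------  ---------  --------------
not_detected  x              x          +
strong        +              x          +

level         probe_info_present  direct_annotation  cross_resource_corroboration  ...
```

Reading the level table: *strong* is supported by two agreeing annotations
(`+` under corroboration), has direct support, but is opposed (`x` under
unopposed) by the not-detected record GXD:0003; *not detected* rests on a
single record (`x` under corroboration) that every other annotation opposes.
The biologist — not the software — weighs that up. Add `--full` to also print
the engine's arguments with their grounded statuses, `--format json` to get
the evidence ids behind every cell (the machine-readable "mouse-over"), and
`--mode level` to compare at level rather than presence granularity.

Reconciling the bundled two-expert scheme scores:

```bash
$ argudas reconcile --schemes demo/schemes.json
schemes              68
exact                16
adjacent             33
disagree             19
broad_agreement_pct  72
disagree_pct         28
```

Of 68 schemes the two experts give the same score to 16 and an adjacent score
to a further 33 — broad agreement on 72% of the schemes, marked disagreement
on the remaining 28%.

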