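# belkit

Tools for corpora written in the Biological Expression Language (BEL 1.0),
the systems-biology notation that records causal findings as
subject–relationship–object triples over namespace-grounded entities —
`p(HGNC:TIMP2) decreases cat(p(HGNC:MMP2))` says that the TIMP2 protein
decreases the catalytic activity of MMP2.  A BEL *nanopub* pairs such a
statement with its PubMed citation and the evidence sentence it was curated
from; collections of nanopubs are the training and evaluation material for
automated relationship-extraction systems, as in the BioCreative V BEL track.

`belkit` is for people who build or evaluate such systems and such corpora.
It provides:

* **Parsing, validation and rendering** of BEL 1.0 terms and statements —
  short and long function spellings (`p()` / `proteinAbundance()`), arrow
  shorthands (`->`, `=>`, `-|`, `=|`), quoting rules, arity and
  namespace–function compatibility checks (ChEBI only under `a()`, MeSH
  diseases only under `path()`, …).
* **Canonicalization** under the track's equivalence rules: `directly*`
  relationships fold into their plain forms, every specific activity
  function (`cat`, `kin`, `tscript`, …) maps to `act()`, `pmod` keeps only
  its type code, translocation compartments are dropped, orthologous genes
  collapse via a user-supplied equivalence map, and complex members sort.
* **Cascade scoring**: predictions are matched against gold statements per
  sentence at term, function, relationship and full-statement granularity
  (plus argument-free secondary variants), micro-averaged into
  precision/recall/F per level, so partially correct output earns partial
  credit.
* **Corpus I/O and selection**: the tab-separated `.tab` / `.BEL` /
  `.sentence` formats and the sentence-classification format with its
  fully-implies-partially label invariant; the base-corpus filters (PubMed
  citation, 36–425-character evidence, at most four nanopubs per evidence
  text, namespace/entity/function budget); category statistics with
  whole-percent shares.
* **Inter-annotator agreement**: Cohen's kappa
  (κ = (p<sub>o</sub> − p<sub>e</sub>)/(1 − p<sub>e</sub>)) for
  supportiveness labels, cascade-F for statement corpora.
* **Tri-occurrence retrieval**: candidate evidence windows of one or two
  sentences containing both statement entities and a polarity trigger word,
  newest publication first.
* **Synthetic corpora**: quota-exact generators for nanopub corpora,
  manifest-tracked perturbations for scorer calibration, and paired
  annotator labelings at a target kappa.

## Worked example

```python
from belkit import AnnotationSet, parse_statement, score

gold = AnnotationSet.from_pairs(
    [("s1", parse_statement("cat(p(MGI:Crk)) directlyIncreases p(MGI:Bcar1, pmod(P))"))]
)
pred = AnnotationSet.from_pairs(
    [("s1", parse_statement("act(p(MGI:Crk)) -> p(MGI:Bcar1, pmod(P, S, 41))"))]
)
for level, tp, fp, fn, p, r, f in score(gold, pred).as_rows():
    print(f"{level:24s} tp={tp} fp={fp} fn={fn} F={f:.2f}")
```

```
term                     tp=2 fp=0 fn=0 F=1.00
function                 tp=2 fp=0 fn=0 F=1.00
function_secondary       tp=2 fp=0 fn=0 F=1.00
relationship             tp=1 fp=0 fn=0 F=1.00
relationship_secondary   tp=1 fp=0 fn=0 F=1.00
statement                tp=1 fp=0 fn=0 F=1.00
```

The prediction differs from the gold statement in its activity function,
arrow shorthand and pmod arguments — all absorbed by canonicalization, so it
earns full credit at every cascade level.  Flip the predicted relationship
to `decreases` and the term and function levels stay at F=1.00 while the
relationship and statement levels drop to 0.00: that is the cascade's
partial credit at work.

The `examples/` directory holds one short script per capability (parsing,
scoring, corpus building, agreement, retrieval); each prints its results
with a note on what they mean.  The same functionality is available from the
shell via the `belkit` command (`parse`, `validate`, `simplify`, `evaluate`,
`convert`, `filter`, `stats`, `iaa`, `retrieve`, `synth` subcommands).

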