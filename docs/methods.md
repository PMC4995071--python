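# Methods

This note records the models, conventions and deliberate design choices
behind `belkit`, in the order a user meets them.

## The language model

BEL 1.0 statements are triples `subject relationship object` where the
object may be one nested statement (depth is capped at one: nested
statements occur in curation practice only as direct objects, and deeper
nesting is rejected rather than guessed).  Terms apply a function to a
namespace-grounded entity (`HGNC:IL6`), to inner terms, or — for
`rxn()` — to reactant and product lists.  The grammar implemented here
is the fragment actually used in the extraction corpora: the five
abundance functions, `complex`/`composite`, the modification terms
(`pmod`, `sub`, `trunc`, `fus`), the transformation family
(`deg`, `sec`, `surf`, `tloc`, `rxn`), ten activity functions, and the
`bp`/`path` process functions.

Parsing conventions:

* short and long spellings are interchangeable and parse to identical
  ASTs; `microRNAabundance` (lower-case *a*, found in older material) is
  accepted as an alias of `microRNAAbundance`;
* both `'` and `"` delimit quoted names; Unicode curly quotes, dashes
  and non-breaking spaces normalize to ASCII before tokenizing, because
  corpus files in the wild contain them;
* whitespace between tokens is insignificant, including inside arrow
  shorthands (`= >` is accepted for `=>`);
* a name must be quoted exactly when it contains a character outside
  `[A-Za-z0-9_]`; rendering quotes with `"` only when required, so
  `parse(render(x)) == x` holds for every valid AST;
* function and namespace codes match case-sensitively; namespaces are an
  open set (no dictionary resolution), with a configurable restriction
  list available at validation time.

Validation reports violations as data, never exceptions: arity rules per
function family, modification-argument rules (a pmod position requires a
residue; `sub` needs ref/position/alt; …), the nesting cap, and the
namespace–function compatibility rules (ChEBI only under `a()`, MESHD
only under `path()`, GOBP only under `bp()`, gene namespaces only under
`g`/`r`/`m`/`p`).  Whether a gene-namespace name denotes a microRNA —
which bars it from `p()` — is decided by a `MIR` name-prefix heuristic,
since namespaces are opaque here.  `composite()` is allowed only at term
top level; nothing in the corpora ever nests it.

## Canonicalization

The scorer compares statements after five equivalence rewrites:
`directly*` relationships fold into their unspecific forms; the activity
family collapses to `act()`; `pmod` keeps only its type code;
translocation-class functions drop their compartment arguments, with
`sec()`/`surf()` rewriting to a bare `tloc()` (the evaluation treats
translocation generically; the rewrite is configurable off); and gene
entities fold to equivalence-class labels when an orthology map is
supplied.  The map is a three-column file (namespace, name, class);
unmapped entities stay distinct.  `complex`/`composite` members are
additionally sorted by canonical rendering after entity mapping, so
member order never distinguishes equivalent curations — whether the
original evaluation sorted members is unrecorded; sorting is the choice
that makes equivalent curations compare equal.  The transform is
idempotent and never changes entity counts or term arity.

## Cascade scoring

Gold and predicted statements are grouped by sentence ID, canonicalized,
decomposed into unit sets per level, and matched as sets; tp/fp/fn are
summed over sentences (micro-averaging, the standard choice in this
evaluation tradition; whether the original scorer micro- or
macro-averaged is not recorded, so this is an assumption).  Units being
sets, duplicated predictions neither help nor hurt; precision is 1 by
convention when nothing is predicted, recall 1 when there is no gold.

Levels, coarse to fine:

| level | unit |
|---|---|
| term | each namespace entity in the statement |
| function_secondary | each non-abundance function code used |
| function | (code, contained entity set) for `act`, `tloc`, `deg`, `complex` and pmod carriers |
| relationship_secondary | relationship + unordered pair of side entity sets |
| relationship | (subject entity set, relationship, object entity set) |
| statement | the whole canonical rendering |

The two `*_secondary` levels appear in the published agreement tables
but are nowhere defined; the argument-free variants above are **this
package's definition**, chosen so each secondary level is a strict
coarsening of its primary level.  The relationship level deliberately
strips functions from the entity sets, making it strictly coarser than
the statement level — consistent with relation-extraction F-scores
exceeding full-statement F-scores in practice.  A nested statement
contributes its inner relationship as an additional relationship-level
unit.  Process functions (`bp`, `path`) and plain abundances carry no
function-level credit.

## Corpus formats and selection

The `.tab` format has five columns (BEL-ID, statement, sentence ID,
evidence sentence, PMID); `.BEL` and `.sentence` split the same content.
The published material shows no header convention, so a header row is
optional on read (recognized by canonical column names or a non-numeric
PMID field) and always written; embedded tabs/newlines in evidence are
escaped `\t`/`\n`.  The classification format column order (bel_id,
statement, pmid, excerpt, fully, partially) follows the order in which
the fields are described with the corpora.  The two-sentence excerpt
limit is checked with a naive splitter (terminal punctuation + space +
capital) — a documented heuristic, warning by default.

Selection filters (defaults): PubMed citation present; evidence length
36–425 characters inclusive (measured in Unicode code points after
trimming; whether the original pipeline normalized whitespace first is
unrecorded); at most **four** nanopubs per evidence text ("fewer than
five"); only the four causal relationship types; only HGNC, MGI, EGID,
MESHD, CHEBI, GOBP entities in subject/object terms; at most four
entity occurrences (`tloc` compartments exempt from both the count and
the whitelist, since curated statements keep GOCC/MESHCL locations while
the restriction names only subject/object terms); no
`composite()`/`rxn()`; optionally no protein variants (sub/trunc/fus),
as in the re-annotated evaluation profiles.  Deduplication on
(canonical statement, evidence, PMID) runs first, keeping the smallest
BEL-ID so the kept set is order-independent; every rejected record
carries the full list of rules it violated.

Statistics tally term types per entity occurrence by enclosing function
(`p`→P, `a`→A, `bp`, `path`; g/r/m abundances and named complexes go to
extra columns excluded from the four-way share), the activity family
folded to `act` and `sec`/`surf` to `tloc`, and relationships with
`directly*` folded in.  Shares are whole percents, rounded half-up.

## Agreement

Binary Cohen's kappa only: the two supportiveness tiers are analysed as
separate binary problems.  p<sub>e</sub> is the product-of-marginals
chance agreement; when p<sub>e</sub> = 1 (both annotators constant and
identical) kappa is reported as 1.  Items present for only one annotator
are excluded with a warning rather than counted as disagreement.
Statement-corpus agreement delegates to the cascade scorer with the
first annotator as gold; F is invariant under swapping.  The published
agreement tables for the re-annotated corpora rest on unpublished
annotation pairs, so their specific values are not reproducible; the
suite instead verifies the machinery (exact arithmetic on the symmetric
18/2/2/18 table, parameter recovery from simulated pairs, swap and
relabeling invariance).

## Retrieval

A candidate excerpt is a window of one or two consecutive sentences of
one document containing a synonym of a subject-side entity, a synonym of
an object-side entity, and a trigger word of the statement's simplified
polarity, in any order and position within the window (the original
system's word-order behaviour is unrecorded; anywhere-in-window is
implemented).  Matching is token-boundary and case-insensitive, exact on
synonyms and stem-prefix on triggers; the shipped trigger lexicon is an
editable artifact default, not published data.  Two-sentence windows are
returned only when neither component sentence qualifies alone, windows
never duplicate, and results sort newest publication date first (ISO
8601; undated documents last), ties on (PMID, window start), capped at
ten.  Real named-entity recognition is out of scope; the synonym
dictionary stands in for it.

## Synthetic corpora

The generator allocates category counts by largest remainder (quota
sampling, not i.i.d.), so marginal assertions in tests are exact and
never flake.  Defaults mirror the published training-corpus shape:
term shares 87/8/4/1 (P/A/bp/path), function mix
act 0.69 / pmod 0.155 / complex 0.082 / tloc 0.045 / deg 0.028 at
0.825 functions per statement, increases share 0.73 with a 0.2
`directly*` fraction, 1–3 statements per sentence.  Statements are
two-sided (one entity per side; `complex` sides carry two), entities are
drawn without replacement within a sentence from reserved-style
vocabularies (`HGNC:GENE0001`, `CHEBI:CHEM0001`, …) to avoid colliding
with real symbols, and evidence sentences embed the entity surface
forms plus a polarity trigger so retrieval tests reuse the same
fixtures.  Evidence lengths and structure keep every generated record
inside the default selection filters.  What the generator does *not*
emulate: linguistically realistic text, co-reference evidence, nested
statements, protein variants, real synonymy — so passing tests
demonstrate the machinery's correctness, not performance on real prose.

Perturbation applies at most one structural edit per statement
(precedence drop > flip > swap > drop-function > pmod-noise; each edit
fires independently at its configured rate and inapplicable draws fall
through).  The manifest records each edit together with per-level
(tp, fp, fn) expectations derived by pure counting from the edit
semantics — an oracle independent of the scorer's canonicalize-and-match
path.  The arithmetic is exact under the generator's guarantees
(distinct entities per statement, fresh swap targets) plus one
precondition: one statement per sentence, since units of co-sentential
statements could otherwise coincide at the secondary levels.
`expected_report` enforces that precondition.  pmod-argument noise is
expected to cost nothing, which is precisely what it verifies about the
canonicalizer.

Annotator pairs are drawn from the symmetric 2×2 distribution with
cells p² + κpq, pq(1−κ), pq(1−κ), q² + κpq, whose analytic kappa equals
the target; quota filling makes the realized kappa exact whenever the
cell expectations are integral (the 18/2/2/18 table at n=40,
prevalence 0.5, κ=0.8), multinomial sampling serves recovery
experiments.  Infeasible (κ, prevalence) combinations (a negative cell)
raise.

## Numerical conventions

Printed ratios round half-up: shares to whole percents, CLI ratios to
two decimals, kappa to two decimals and observed agreement to one in
the agreement reports.  Precision/recall are 1 when their denominator
is 0; F is 0 when p + r = 0.  All randomness flows through
`numpy.random.default_rng` seeded from explicit config fields; equal
seeds give byte-identical outputs.

## Problem sizes

The shipped checks use the sizes at which their guarantees are exact or
tight: the full 36-expression inventory for grammar coverage; the
published count tables (22 966 term, 9 133 function, 11 068 relationship
occurrences; 1 554 labeled excerpts) for the share and label arithmetic;
200 single-statement sentences for manifest calibration; n=2000 for
stochastic kappa recovery; ~1 000 records for filter idempotence; and
~10 000 generated statements for the parse/render round trip.

## Known limitations

* BEL v2.0 (variants, `regulates`, location modifiers) is out of scope.
* No namespace dictionary resolution; entity names are opaque strings.
* The microRNA restriction is a name-prefix heuristic.
* The secondary cascade levels are this package's reconstruction.
* The sentence splitter and the retrieval matcher are deliberately
  shallow stand-ins for real NLP components.
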