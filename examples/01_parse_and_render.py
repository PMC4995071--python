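"""Parse BEL 1.0 statements, validate them, and render them back.

BEL expresses causal biological findings as subject–relationship–object
triples over namespace-grounded entities (HGNC genes, ChEBI chemicals,
GO biological processes, MeSH diseases).  The parser accepts short and
long function spellings interchangeably and arrow shorthands for the
four relationship types.
"""

from belkit import parse_statement, parse_term, render, validate

stmt = parse_statement("cat(p(MGI:Crk)) => p(MGI:Bcar1, pmod(P))")
print("parsed:     ", render(stmt))
print("long form:  ", render(stmt, style="long"))
# The catalytic activity of mouse Crk directly increases phosphorylated
# Bcar1 — the '=>' arrow is the directlyIncreases shorthand.

term = parse_term('tloc(p(HGNC:NFE2L2), MESHCL:Cytoplasm, MESHCL:"Cell Nucleus")')
print("violations: ", validate(term))
# An empty violation list: the translocation term is structurally valid
# and its namespaces are compatible with their enclosing functions.

bad = parse_term("p(CHEBI:water)")
for v in validate(bad):
    print("violation:  ", v)
# Chemicals belong under the generic abundance function a(), not p() —
# the validator reports the incompatibility as data rather than raising.
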