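"""Tri-occurrence evidence retrieval for a BEL statement.

Candidate excerpts (one or two consecutive sentences) must contain a
subject entity synonym, an object entity synonym, and a trigger word of
the statement's polarity; results come back newest publication first,
at most ten, ready to be turned into unlabeled classification records
for manual supportiveness annotation.
"""

from belkit import SentenceDoc, TriggerLexicon, find_excerpts, label_template, parse_statement

stmt = parse_statement("p(HGNC:TNF) increases p(HGNC:IL6)")

docs = [
    SentenceDoc("101", "2014-03-01", ("TNF strongly induces IL6 in hepatocytes.",)),
    SentenceDoc(
        "102",
        "2016-06-01",
        (
            "We first characterized TNF signalling.",
            "Stimulation upregulated IL6 within two hours.",
        ),
    ),
    SentenceDoc("103", "2010-01-01", ("IL6 levels were unchanged in controls.",)),
]

for hit in find_excerpts(stmt, docs, triggers=TriggerLexicon.default()):
    print(f"PMID {hit.pmid} ({hit.date}, {hit.n_sentences} sentence(s)): {hit.text}")
# The 2016 two-sentence window ranks first (newest date); the entity
# mention and the trigger may sit in different adjacent sentences.
# PMID 103 never matches: it lacks TNF and any increase trigger.

template = label_template(stmt, find_excerpts(stmt, docs)[0], bel_id="b1")
print("template labels set?", template.labeled)
# False — the record carries statement, PMID and excerpt, with the
# fully/partially supportive labels left for the human annotator.
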