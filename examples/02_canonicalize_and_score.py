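"""Canonicalize statements under the evaluation equivalence rules and
score a prediction against a gold annotation with the cascade model.

The evaluation treats directlyIncreases/increases as equal, folds every
specific activity function into act(), keeps only the pmod type code,
and drops translocation compartments — so a prediction that differs
from the gold statement only in those respects earns full credit, and a
partially correct one earns credit at the coarser cascade levels.
"""

from belkit import (
    AnnotationSet,
    SimplifyConfig,
    parse_statement,
    render,
    score,
    simplify,
)

gold_text = "cat(p(MGI:Crk)) directlyIncreases p(MGI:Bcar1, pmod(P))"
pred_text = "act(p(MGI:Crk)) -> p(MGI:Bcar1, pmod(P, S, 41))"

config = SimplifyConfig.track()
print("gold canonical:", render(simplify(parse_statement(gold_text), config)))
print("pred canonical:", render(simplify(parse_statement(pred_text), config)))
# Both canonicalize to the same statement, so they compare equal.

gold = AnnotationSet.from_pairs([("s1", parse_statement(gold_text))])
pred = AnnotationSet.from_pairs([("s1", parse_statement(pred_text))])
report = score(gold, pred)
for level, tp, fp, fn, p, r, f in report.as_rows():
    print(f"{level:24s} tp={tp} fp={fp} fn={fn} F={f:.2f}")
# F=1.00 at every level: the simplifications absorb all the differences.

wrong = AnnotationSet.from_pairs(
    [("s1", parse_statement("act(p(MGI:Crk)) decreases p(MGI:Bcar1, pmod(P))"))]
)
report = score(gold, wrong)
print("\nwith flipped polarity:")
for level, tp, fp, fn, p, r, f in report.as_rows():
    print(f"{level:24s} F={f:.2f}")
# Terms and functions still match (F=1.00) but the relationship and the
# full statement do not (F=0.00) — that is the cascade's partial credit.
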