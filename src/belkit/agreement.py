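"""Inter-annotator agreement.

For label corpora (fully/partially supportive flags) agreement is the
observed proportion of matching labels ``po`` corrected for chance with
Cohen's kappa: ``kappa = (po - pe) / (1 - pe)`` where ``pe`` is the
agreement expected if both annotators labeled independently with their
observed marginals.  Each supportiveness tier is a separate binary
analysis.

For statement corpora agreement is the cascade F-score: one annotator's
statements are taken as the gold standard, the other's as a prediction,
and the scorer reports precision/recall/F per cascade level; F is
invariant under swapping annotators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Mapping, Optional, Sequence, Tuple

from .evaluate import AnnotationSet, EvalReport, score_as_iaa
from .simplify import SimplifyConfig

__all__ = [
    "AgreementResult",
    "kappa",
    "pairwise_label_iaa",
    "pairwise_statement_iaa",
]


@dataclass(frozen=True)
class AgreementResult:
    """Observed agreement, chance agreement and Cohen's kappa over n
    aligned items."""

    n: int
    po: float
    pe: float
    kappa: float


def kappa(labels_a: Sequence[bool], labels_b: Sequence[bool]) -> AgreementResult:
    """Cohen's kappa for two aligned binary label sequences.

    ``pe`` sums the products of the two annotators' class marginals.
    When ``pe == 1`` (both annotators constant and equal) kappa is
    reported as 1.0 if agreement is perfect; a degenerate disagreeing
    pair raises instead.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label sequences differ in length ({len(labels_a)} vs {len(labels_b)})"
        )
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty label sequences")
    a = [bool(x) for x in labels_a]
    b = [bool(x) for x in labels_b]
    po = sum(x == y for x, y in zip(a, b)) / n
    pa, pb = sum(a) / n, sum(b) / n
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        if po == 1.0:
            return AgreementResult(n=n, po=po, pe=pe, kappa=1.0)
        raise ValueError("chance agreement is 1 but observed agreement is not")
    k = (po - pe) / (1 - pe)
    return AgreementResult(n=n, po=po, pe=pe, kappa=k)


def _tier_labels(
    records: Mapping[str, bool]
) -> Mapping[str, bool]:
    return records


def pairwise_label_iaa(
    annotations: Mapping[str, Mapping[str, bool]],
) -> Dict[Tuple[str, str], AgreementResult]:
    """Agreement per unordered annotator pair on shared items.

    ``annotations`` maps annotator name to ``{item_id: label}`` for one
    tier.  Items missing from either annotator are excluded with a
    warning; pairs with no overlap raise.
    """
    results: Dict[Tuple[str, str], AgreementResult] = {}
    for name_a, name_b in combinations(sorted(annotations), 2):
        items_a, items_b = annotations[name_a], annotations[name_b]
        shared = sorted(set(items_a) & set(items_b))
        if not shared:
            raise ValueError(f"annotators {name_a!r} and {name_b!r} share no items")
        missing = len(set(items_a) ^ set(items_b))
        if missing:
            warnings.warn(
                f"{missing} items present for only one of {name_a!r}/{name_b!r} "
                "were excluded",
                stacklevel=2,
            )
        results[(name_a, name_b)] = kappa(
            [items_a[i] for i in shared], [items_b[i] for i in shared]
        )
    return results


def pairwise_statement_iaa(
    annotations: Mapping[str, AnnotationSet],
    config: Optional[SimplifyConfig] = None,
) -> Dict[Tuple[str, str], EvalReport]:
    """Cascade-F agreement per unordered annotator pair: the first
    (alphabetically) is the gold standard, the second the prediction."""
    results: Dict[Tuple[str, str], EvalReport] = {}
    for name_a, name_b in combinations(sorted(annotations), 2):
        results[(name_a, name_b)] = score_as_iaa(
            annotations[name_a], annotations[name_b], config
        )
    return results
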