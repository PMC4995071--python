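"""Published reference counts shipped with the package.

The training-corpus category distribution and the classification-corpus
label counts are published alongside the corpora; they serve as inputs
for reproducing the corpus statistics (percentage shares, label
arithmetic) without downloading the corpora themselves.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List

from .corpus_io import ClassificationRecord
from .parser import parse_statement


def _read_data(name: str) -> List[List[str]]:
    text = resources.files("belkit").joinpath(f"data/{name}").read_text("utf-8")
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            rows.append(line.split("\t"))
    return rows


def load_training_distribution() -> Dict[str, Dict[str, int]]:
    """``{category: {key: count}}`` for the published training corpus:
    term types (P/A/bp/path), function types, relationship types and
    corpus size."""
    out: Dict[str, Dict[str, int]] = {}
    for category, key, count in _read_data("training_distribution.tsv"):
        out.setdefault(category, {})[key] = int(count)
    return out


def load_classification_counts() -> Dict[str, int]:
    """Published label counts of the sentence-classification corpus."""
    return {key: int(count) for key, count in _read_data("classification_counts.tsv")}


def reconstruct_classification_records() -> List[ClassificationRecord]:
    """A corpus of placeholder statement–excerpt records realizing the
    published label counts, for exercising the label arithmetic.

    Synthetic stand-in: the real excerpts are not redistributed here;
    only the label marginals are reproduced.
    """
    counts = load_classification_counts()
    n, fully, partially = counts["n"], counts["fully_true"], counts["partially_true"]
    if not fully <= partially <= n:
        raise ValueError("inconsistent published counts")
    stmt = parse_statement("p(HGNC:GENEA) increases p(HGNC:GENEB)")
    records = []
    for i in range(n):
        is_fully = i < fully
        is_partially = i < partially  # fully-true records come first
        records.append(
            ClassificationRecord(
                bel_id=f"C{i + 1:05d}",
                statement=stmt,
                pmid="10000000",
                excerpt="GENEA markedly increased GENEB in treated cells.",
                fully_supportive=is_fully,
                partially_supportive=is_partially,
            )
        )
    return records
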