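"""The canonical BEL 1.0 expression inventory shipped with the package:
one example per function and relationship, in short and long spelling.
Used by the grammar-coverage checks and the worked examples."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import List


@dataclass(frozen=True)
class InventoryEntry:
    kind: str  # "term" or "statement"
    short: str
    long: str


def load_inventory() -> List[InventoryEntry]:
    text = (
        resources.files("belkit").joinpath("data/bel10_examples.tsv").read_text("utf-8")
    )
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, short, long = line.split("\t")
        entries.append(InventoryEntry(kind, short, long))
    return entries
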