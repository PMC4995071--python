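"""Canonicalization under the BEL-track evaluation equivalence rules.

Predicted and gold statements are compared after five simplifications:

1. direct relationships fold into their unspecific forms
   (``directlyIncreases`` -> ``increases``);
2. every specific activity function (``cat``, ``kin``, ``tscript``, ...)
   maps to the generic ``act()``;
3. ``pmod`` keeps only its type code (``pmod(P, T, 202)`` -> ``pmod(P)``);
4. translocation-class functions drop their compartment arguments, with
   ``sec()``/``surf()`` rewriting to a bare ``tloc()``;
5. orthologous gene entities collapse to a shared equivalence-class
   label when a map is supplied.

``complex``/``composite`` members are additionally sorted by canonical
rendering so member order never distinguishes equivalent curations.
The transform is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

from .model import (
    ACTIVITY_FUNCTIONS,
    BelStatement,
    BelTerm,
    GENE_NAMESPACES,
    Modification,
    NamespaceEntity,
    render,
    render_term,
)

__all__ = [
    "OrthologyMap",
    "SimplifyConfig",
    "simplify",
    "simplify_term",
    "statements_equivalent",
]

#: namespace used for equivalence-class labels after ortholog folding
ORTHOLOG_NAMESPACE = "ORTH"


@dataclass(frozen=True)
class OrthologyMap:
    """Mapping from (namespace, name) to an equivalence-class label.

    Entities absent from the map form singleton classes (they are left
    untouched).  The file format is three tab-separated columns:
    namespace, name, class label.
    """

    entries: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def label(self, entity: NamespaceEntity) -> Optional[str]:
        return self.entries.get((entity.namespace, entity.name))

    @classmethod
    def from_file(cls, path) -> "OrthologyMap":
        entries: Dict[Tuple[str, str], str] = {}
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            ns, name, label = parts
            entries[(ns, name)] = label
        return cls(entries)


@dataclass(frozen=True)
class SimplifyConfig:
    """Which equivalence rules to apply.  The default enables everything
    except ortholog folding, which needs a map."""

    apply_ortholog: bool = False
    map: Optional[OrthologyMap] = None
    collapse_direct: bool = True
    collapse_activity: bool = True
    strip_pmod_args: bool = True
    strip_tloc_args: bool = True

    def __post_init__(self) -> None:
        if self.apply_ortholog and self.map is None:
            raise ValueError("apply_ortholog requires an orthology map")

    @classmethod
    def track(cls, map: Optional[OrthologyMap] = None) -> "SimplifyConfig":
        """The full evaluation configuration (ortholog folding included
        when a map is given)."""
        return cls(apply_ortholog=map is not None, map=map)

    @classmethod
    def identity(cls) -> "SimplifyConfig":
        return cls(
            collapse_direct=False,
            collapse_activity=False,
            strip_pmod_args=False,
            strip_tloc_args=False,
        )


def _map_entity(entity: NamespaceEntity, config: SimplifyConfig) -> NamespaceEntity:
    if (
        config.apply_ortholog
        and entity.namespace in GENE_NAMESPACES
    ):
        label = config.map.label(entity)
        if label is not None:
            return NamespaceEntity(ORTHOLOG_NAMESPACE, label)
    return entity


def _simplify_modification(mod: Modification, config: SimplifyConfig) -> Modification:
    if mod.kind == "pmod" and config.strip_pmod_args:
        return Modification("pmod", pmod_type=mod.pmod_type)
    if mod.kind == "fus" and mod.fus_partner is not None and config.apply_ortholog:
        return replace(mod, fus_partner=_map_entity(mod.fus_partner, config))
    return mod


def simplify_term(term: BelTerm, config: SimplifyConfig) -> BelTerm:
    function = term.function
    locations = term.locations
    if config.collapse_activity and function in ACTIVITY_FUNCTIONS:
        function = "act"
    if config.strip_tloc_args and function in ("tloc", "sec", "surf"):
        function = "tloc"
        locations = ()

    entity = _map_entity(term.entity, config) if term.entity is not None else None
    inner = tuple(simplify_term(t, config) for t in term.inner_terms)
    if function in ("complex", "composite"):
        inner = tuple(sorted(inner, key=render_term))
    mods = tuple(_simplify_modification(m, config) for m in term.modifications)
    reactants = tuple(simplify_term(t, config) for t in term.reactants)
    products = tuple(simplify_term(t, config) for t in term.products)
    return BelTerm(
        function=function,
        entity=entity,
        inner_terms=inner,
        modifications=mods,
        locations=locations,
        reactants=reactants,
        products=products,
    )


_DIRECT = {"directlyIncreases": "increases", "directlyDecreases": "decreases"}


def simplify(statement: BelStatement, config: SimplifyConfig) -> BelStatement:
    """Return the canonical form of ``statement`` under ``config``.

    Idempotent; never changes subject/object arity or the term count.
    """
    relationship = statement.relationship
    if config.collapse_direct:
        relationship = _DIRECT.get(relationship, relationship)
    obj: Union[BelTerm, BelStatement]
    if statement.object_is_statement:
        obj = simplify(statement.object, config)
    else:
        obj = simplify_term(statement.object, config)
    return BelStatement(
        subject=simplify_term(statement.subject, config),
        relationship=relationship,
        object=obj,
    )


def statements_equivalent(
    a: BelStatement, b: BelStatement, config: Optional[SimplifyConfig] = None
) -> bool:
    """True iff the two statements are equal after canonicalization."""
    config = config or SimplifyConfig.track()
    return render(simplify(a, config)) == render(simplify(b, config))
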