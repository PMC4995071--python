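import pytest
from hypothesis import strategies as st

from belkit.model import BelStatement, BelTerm, Modification, NamespaceEntity


# --- hypothesis strategies for valid BEL ASTs -----------------------------

_NAME_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_"
    " -,()[]+/.'"
)

names = st.text(alphabet=_NAME_ALPHABET, min_size=1, max_size=20).filter(
    lambda s: s.strip() == s or True
)
gene_entities = st.builds(
    NamespaceEntity, st.sampled_from(["HGNC", "MGI", "RGD", "EGID"]), names
)
chem_entities = st.builds(NamespaceEntity, st.just("CHEBI"), names)
process_entities = st.builds(NamespaceEntity, st.just("GOBP"), names)
disease_entities = st.builds(NamespaceEntity, st.just("MESHD"), names)
location_entities = st.builds(
    NamespaceEntity, st.sampled_from(["GOCC", "MESHCL"]), names
)

aa_codes = st.sampled_from(["A", "C", "D", "E", "K", "N", "S", "T", "Y"])

pmods = st.builds(
    lambda t, residue, pos: Modification(
        "pmod",
        pmod_type=t,
        residue=residue if (residue or pos is None) else "S",
        position=pos if residue else None,
    ),
    st.sampled_from(["P", "A", "H"]),
    st.one_of(st.none(), aa_codes),
    st.one_of(st.none(), st.integers(1, 2000)),
)
subs = st.builds(
    lambda r, p, a: Modification("sub", sub_ref=r, position=p, sub_alt=a),
    aa_codes,
    st.integers(1, 2000),
    aa_codes,
)
truncs = st.builds(lambda p: Modification("trunc", position=p), st.integers(1, 2000))
fusions = st.builds(
    lambda partner, bps: Modification("fus", fus_partner=partner, fus_breakpoints=bps),
    gene_entities,
    st.one_of(st.none(), st.tuples(st.integers(1, 5000), st.integers(1, 5000))),
)

proteins = st.builds(
    lambda e, mods: BelTerm("p", entity=e, modifications=mods),
    gene_entities,
    st.one_of(
        st.just(()),
        st.tuples(st.one_of(pmods, subs, truncs, fusions)),
    ),
)
simple_abundances = st.one_of(
    proteins,
    st.builds(lambda e: BelTerm("a", entity=e), chem_entities),
    st.builds(
        lambda fn, e: BelTerm(fn, entity=e),
        st.sampled_from(["g", "r"]),
        gene_entities,
    ),
)
complexes = st.one_of(
    st.builds(
        lambda e: BelTerm("complex", entity=e),
        st.builds(NamespaceEntity, st.just("NCH"), names),
    ),
    st.builds(
        lambda members: BelTerm("complex", inner_terms=tuple(members)),
        st.lists(proteins, min_size=2, max_size=3),
    ),
)
abundances = st.one_of(simple_abundances, complexes)

activities = st.builds(
    lambda fn, inner: BelTerm(fn, inner_terms=(inner,)),
    st.sampled_from(
        ["act", "cat", "chap", "gtp", "kin", "pep", "phos", "ribo", "tscript", "tport"]
    ),
    abundances,
)
transformations = st.one_of(
    st.builds(
        lambda fn, inner: BelTerm(fn, inner_terms=(inner,)),
        st.sampled_from(["deg", "sec", "surf"]),
        simple_abundances,
    ),
    st.builds(
        lambda inner, locs: BelTerm("tloc", inner_terms=(inner,), locations=locs),
        simple_abundances,
        st.one_of(st.just(()), st.tuples(location_entities, location_entities)),
    ),
)
processes = st.one_of(
    st.builds(lambda e: BelTerm("bp", entity=e), process_entities),
    st.builds(lambda e: BelTerm("path", entity=e), disease_entities),
)

terms = st.one_of(abundances, activities, transformations, processes)

relationships = st.sampled_from(
    ["increases", "decreases", "directlyIncreases", "directlyDecreases"]
)

simple_statements = st.builds(BelStatement, terms, relationships, terms)
statements = st.one_of(
    simple_statements,
    st.builds(BelStatement, terms, relationships, simple_statements),
)


@pytest.fixture(scope="session")
def inventory():
    from belkit.inventory import load_inventory

    return load_inventory()


@pytest.fixture(scope="session")
def small_corpus():
    """A deterministic synthetic corpus shared across tests."""
    from belkit.synth import SynthConfig, gen_corpus

    return gen_corpus(SynthConfig(n_sentences=60, seed=42))
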