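import pytest

from herbnet.datasets import (
    bundled_compounds,
    bundled_targets,
    bundled_whitelist,
    split_by_herb,
    synthetic_interaction_table,
)


@pytest.fixture(scope="session")
def compounds():
    """The bundled 65-compound ADME inventory."""
    return bundled_compounds()


@pytest.fixture(scope="session")
def per_herb_compounds(compounds):
    """Per-herb expansion (73 rows: shared compounds listed once per herb)."""
    return split_by_herb(compounds)


@pytest.fixture(scope="session")
def whitelist():
    return bundled_whitelist()


@pytest.fixture(scope="session")
def targets():
    """The bundled 185-target mapping."""
    return bundled_targets()


@pytest.fixture(scope="session")
def interactions():
    """Deterministic synthetic 739-edge interaction stand-in."""
    return synthetic_interaction_table()


@pytest.fixture(scope="session")
def target_index(interactions):
    index: dict[str, set[str]] = {}
    for r in interactions:
        index.setdefault(r.compound_id, set()).add(r.target_uniprot)
    return index
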