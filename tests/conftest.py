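import numpy as np
import pytest

from phenolic import synth
from phenolic.db import (
    Database,
    GeneFamily,
    OntologyTerm,
    PathwayDef,
    make_database,
)


@pytest.fixture(scope="session")
def small_db() -> Database:
    """Three families, two pathways, tiny ontology."""
    terms = [
        OntologyTerm("T:root", "polyphenol", None),
        OntologyTerm("T:tannin", "tannin", "T:root"),
    ]
    families = [
        GeneFamily("famA", "enzyme A", "profile_hmm", 200.0, 120.0, ("T:root",), "", "models/famA.hmm"),
        GeneFamily("famB", "enzyme B", "sequence_similarity", 150.0, None, ("T:tannin",), "", "models/famB.faa"),
        GeneFamily("famC", "enzyme C", "profile_hmm", 90.0, 50.0, (), "", "models/famC.hmm"),
    ]
    pathways = [
        PathwayDef(1, "ring cleavage", "polymer", "oxic",
                   (frozenset({"famA"}), frozenset({"famB", "famC"}))),
        PathwayDef(2, "demethylation", "monomer", "anoxic",
                   (frozenset({"famB"}),)),
    ]
    return make_database(families, terms, pathways)


@pytest.fixture(scope="session")
def family_fixtures():
    """Two score-separable synthetic protein families (seeded)."""
    return synth.make_protein_families(synth.FamilyFixtureSpec(), seed=11)


@pytest.fixture(scope="session")
def count_fixture():
    """Planted-truth count matrix over the 3x3x3 habitat layout (seeded)."""
    return synth.make_counts(synth.CountFixtureSpec(), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
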