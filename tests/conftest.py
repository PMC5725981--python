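import logging

import pytest

from setfam.catalog import load_catalog
from setfam.homology import ReferenceSet
from setfam.simulate import GeneratorConfig, generate_proteome

logging.getLogger("setfam").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def references():
    return ReferenceSet.load_default()


@pytest.fixture(scope="session")
def bundle(catalog, references):
    """Default-condition synthetic bundle shared across read-only tests."""
    return generate_proteome(GeneratorConfig(seed=5), catalog, references)


@pytest.fixture(scope="session")
def classified(bundle, all_proteins, catalog, references):
    """Full identify -> dedupe -> classify chain on the default bundle."""
    from setfam.classify import classify_all
    from setfam.identification import (deduplicate, find_set_candidates,
                                       merge_interrupted_set_hits)
    hits = merge_interrupted_set_hits(bundle.hits)
    cands = find_set_candidates(all_proteins, hits, synonyms=catalog.synonyms)
    unique = deduplicate(cands, hits, catalog.synonyms)
    return classify_all(unique, hits, catalog, references)


@pytest.fixture(scope="session")
def all_proteins(bundle):
    """Bundle proteins plus the transdecoded transcript ORFs."""
    from setfam.identification import extract_longest_orf
    orfs = [extract_longest_orf(t) for t in bundle.transcripts]
    assert all(o is not None for o in orfs)
    return bundle.proteins + orfs
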