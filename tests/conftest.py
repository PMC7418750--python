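import numpy as np
import pytest

from ontolabel.corpus import doc_from_sentences
from ontolabel.ontology import Terminology, build_type_distribution
from ontolabel.synthetic import WorldSpec, build_world, generate_corpus


@pytest.fixture(scope="session")
def small_world():
    return build_world(WorldSpec(n_classes=2, lexicon_size=30, seed=11))


@pytest.fixture(scope="session")
def small_corpus(small_world):
    docs, gold_spans, gold_tags = generate_corpus(small_world, 120, seed=12)
    return docs, gold_spans, gold_tags


@pytest.fixture()
def drug_terminology():
    t = Terminology("drugbank_toy")
    t.add(("tylenol",), {1})
    t.add(("acetaminophen",), {1})
    t.add(("aspirin",), {1})
    return t


def type_map_for(*terminologies, n_classes=2):
    return build_type_distribution(list(terminologies), n_classes)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
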