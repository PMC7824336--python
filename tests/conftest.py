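import pytest

import entromatch as em


@pytest.fixture(scope="session")
def small_dna_campaign():
    """A small but fully populated DNA campaign: corpus, patterns, model."""
    corpus = em.synthetic_dna_corpus(20_000, seed=11)
    patterns = em.sample_patterns(corpus, [2, 4, 8, 16, 32], 120, seed=12).patterns
    model = em.build_model(
        corpus.text, patterns, domain="dna", seed=12, text_ids=[corpus.identifier]
    )
    records = em.run_campaign(corpus.text, patterns, em.ALGORITHM_IDS, scheme=model.scheme)
    return corpus, patterns, model, records


@pytest.fixture(scope="session")
def dna_scheme_91():
    """A DNA-style discretization input: 91 distinct 2-decimal values in [0, 2].

    Mirrors the published campaign's observation list shape (91 distinct
    rounded entropies, minimum 0, maximum 2.00).
    """
    values = [0.00] + [round(1.00 + i / 100, 2) for i in range(89)] + [2.00]
    assert len(set(values)) == 91
    return values
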