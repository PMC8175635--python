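import random
from types import SimpleNamespace

import pytest

import viromarkov as vm


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def naive_loglik(seq: str, model: vm.MarkovModel) -> float:
    """Independent per-position oracle: explicit window loop, string keys."""
    k = model.order
    terms = []
    s = seq.upper()
    for i in range(len(s) - k):
        w = s[i : i + k + 1]
        if any(c not in "ACGT" for c in w):
            continue
        terms.append(model.log_p(w[:k], w[k]))
    if not terms:
        raise ValueError("no scoreable window")
    return sum(terms) / len(terms)


def naive_revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq.upper()))


@pytest.fixture(scope="session")
def bench():
    """Small fitted two-chain benchmark shared across tests.

    4 genomes x 30 kb per class from order-2 chains at GC 0.35 (virus) and
    0.65 (host); classifier at order 2 with 2 GC bins and a 400-fragment
    bacterial null at 500 bp.
    """
    virus, host, vspec, hspec = vm.two_chain_corpora(
        n_genomes=4, genome_length=30_000, seed=11
    )
    model = vm.ViralMarkovClassifier(virus, host, order=2, n_bins=2)
    null_genome = vm.synthesize_genome(hspec, 400 * 500 + 2, seed=99)
    null = vm.fragment_genomes([("null", null_genome)], 500, label="host").sequences()
    results = model.fit(null_fragments=null)
    return SimpleNamespace(
        virus=virus, host=host, vspec=vspec, hspec=hspec, model=model, results=results
    )
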