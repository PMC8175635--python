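"""Benchmark construction: fragmentation, class mixtures, synthetic
Markov-structured genomes and an error-free paired-read simulator.

The premise of the classifier is that viral and bacterial genomes follow
different Markov chains, so the synthetic benchmark generates "genomes" from
two explicitly different chains (distinct GC content and perturbed
transition rows) and asks the classifier to recover the source.  Everything
here is seed-deterministic, so training, scoring and evaluation run with no
downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .markov import reverse_complement

__all__ = [
    "Fragment",
    "FragmentSet",
    "fragment_genomes",
    "mixture_host_count",
    "build_mixture",
    "GeneratorSpec",
    "gc_biased_spec",
    "synthesize_genome",
    "ReadPair",
    "simulate_read_pairs",
    "two_chain_corpora",
]


@dataclass
class Fragment:
    id: str
    sequence: str
    label: str
    source_genome: str
    offset: int


@dataclass
class FragmentSet:
    """Non-overlapping fixed-length fragments with truth labels."""

    fragments: list[Fragment]
    fragment_length: int
    n_discarded_bp: int = 0

    def __len__(self) -> int:
        return len(self.fragments)

    def sequences(self) -> list[tuple[str, str]]:
        return [(f.id, f.sequence) for f in self.fragments]


def fragment_genomes(
    records: Iterable[tuple[str, str]], fragment_length: int, label: str = "host"
) -> FragmentSet:
    """Split records into consecutive non-overlapping L-bp fragments.

    The trailing remainder (< L bp) of each record is discarded and tallied.
    Fragment ids encode source and 0-based half-open coordinates.
    """
    if fragment_length < 1:
        raise ValueError("fragment length must be >= 1")
    frags: list[Fragment] = []
    discarded = 0
    for rid, seq in records:
        n_full = len(seq) // fragment_length
        discarded += len(seq) - n_full * fragment_length
        for i in range(n_full):
            off = i * fragment_length
            frags.append(
                Fragment(
                    id=f"{rid}:{off}-{off + fragment_length}",
                    sequence=seq[off : off + fragment_length],
                    label=label,
                    source_genome=rid,
                    offset=off,
                )
            )
    return FragmentSet(fragments=frags, fragment_length=fragment_length, n_discarded_bp=discarded)


def mixture_host_count(n_viral: int, viral_fraction: float) -> int:
    """Host fragments to draw so viral fragments are the requested fraction.

    ceil(V·(1−f)/f), with an epsilon guard so exact products (e.g. 9·V at
    f = 0.10) are not pushed over an integer by binary-float error.
    """
    if not 0 < viral_fraction < 1:
        raise ValueError("viral_fraction must be in (0, 1)")
    if n_viral < 1:
        raise ValueError("need at least one viral fragment")
    target = n_viral * (1.0 - viral_fraction) / viral_fraction
    eps = 1e-9 + abs(target) * 1e-12
    return int(math.ceil(target - eps))


def build_mixture(
    viral: FragmentSet,
    host_pool: FragmentSet,
    viral_fraction: float,
    seed: int = 0,
) -> FragmentSet:
    """Combine all viral fragments with host fragments subsampled without
    replacement so that the viral share is ``viral_fraction``."""
    n_host = mixture_host_count(len(viral), viral_fraction)
    if n_host > len(host_pool):
        raise ValueError(
            f"host pool too small: need {n_host} fragments, have {len(host_pool)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(host_pool), size=n_host, replace=False)
    frags = list(viral.fragments) + [host_pool.fragments[i] for i in chosen]
    return FragmentSet(fragments=frags, fragment_length=viral.fragment_length)


@dataclass
class GeneratorSpec:
    """A fully specified generating chain for synthetic genomes."""

    order: int
    transition: np.ndarray
    initial: np.ndarray = None
    target_gc: float | None = None
    name: str = "chain"

    def __post_init__(self):
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (4**self.order, 4):
            raise ValueError(f"transition matrix must be (4^{self.order}, 4), got {t.shape}")
        if (t < 0).any():
            raise ValueError("transition probabilities must be >= 0")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must each sum to 1 (within 1e-12)")
        self.transition = t
        if self.initial is None:
            self.initial = np.full(4**self.order, 1.0 / 4**self.order)
        else:
            self.initial = np.asarray(self.initial, dtype=float)
            if self.initial.shape != (4**self.order,) or not np.isclose(
                self.initial.sum(), 1.0, atol=1e-9
            ):
                raise ValueError("initial distribution must be a length-4^order simplex vector")


def gc_biased_spec(
    order: int,
    gc: float,
    wobble: float = 0.15,
    seed: int = 0,
    name: str | None = None,
) -> GeneratorSpec:
    """A chain whose rows centre on a GC-biased base distribution.

    Each context row is the base distribution [(1-gc)/2, gc/2, gc/2,
    (1-gc)/2] perturbed multiplicatively by exp(wobble·N(0,1)) and
    renormalized, giving distinct context-specific k-mer usage on top of the
    GC signal — the two features the classifier exploits.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    rows = base * np.exp(wobble * rng.standard_normal((4**order, 4)))
    rows /= rows.sum(axis=1, keepdims=True)
    return GeneratorSpec(
        order=order, transition=rows, target_gc=gc, name=name or f"gc{gc:.2f}"
    )


_BASES = np.array(list("ACGT"))


def synthesize_genome(spec: GeneratorSpec, length: int, seed: int = 0) -> str:
    """Sample a sequence of the given length from the generating chain."""
    k = spec.order
    if length < k + 1:
        raise ValueError(f"length must be >= order+1 = {k + 1}")
    rng = np.random.default_rng(seed)
    state = int(rng.choice(4**k, p=spec.initial))
    prefix = [(state >> (2 * (k - 1 - j))) & 3 for j in range(k)]
    out = list(prefix)
    cum = np.cumsum(spec.transition, axis=1)
    cum[:, 3] = 1.0 + 1e-12
    cum_list = [tuple(row) for row in cum]
    mask = 4**k - 1 if k > 0 else 0
    u = rng.random(length - k)
    for i in range(length - k):
        row = cum_list[state]
        ui = u[i]
        x = 0 if ui < row[0] else 1 if ui < row[1] else 2 if ui < row[2] else 3
        out.append(x)
        state = ((state << 2) | x) & mask
    return "".join(_BASES[np.array(out, dtype=np.int64)])


@dataclass
class ReadPair:
    """One error-free mate pair: mate1 is the fragment's leading-strand
    prefix, mate2 the reverse complement of its suffix."""

    id: str
    mate1: str
    mate2: str
    label: str
    source_genome: str
    position: int


def simulate_read_pairs(
    genomes: Sequence[tuple[str, str, str]],
    n_pairs: int,
    read_length: int = 150,
    insert: int = 300,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[ReadPair]:
    """Uniformly sample mate pairs from labelled genomes.

    ``genomes`` is a sequence of (id, sequence, label).  Fragment start
    positions are uniform over all feasible positions pooled across genomes
    (so coverage is proportional to genome length).  ``error_rate`` applies
    independent uniform substitutions to both mates; the default is
    error-free.
    """
    if insert < 2 * read_length:
        raise ValueError(f"insert ({insert}) must be >= 2 x read_length ({read_length})")
    weights = []
    for gid, seq, _ in genomes:
        if len(seq) < insert:
            raise ValueError(f"genome {gid!r} shorter ({len(seq)}) than insert ({insert})")
        weights.append(len(seq) - insert + 1)
    weights = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    which = rng.choice(len(genomes), size=n_pairs, p=weights / weights.sum())
    pairs: list[ReadPair] = []
    for i, g in enumerate(which):
        gid, seq, label = genomes[g]
        pos = int(rng.integers(0, len(seq) - insert + 1))
        frag = seq[pos : pos + insert]
        m1 = frag[:read_length]
        m2 = reverse_complement(frag[insert - read_length :])
        if error_rate > 0:
            m1 = _mutate(m1, error_rate, rng)
            m2 = _mutate(m2, error_rate, rng)
        pairs.append(
            ReadPair(
                id=f"{gid}|{label}|{pos}|{i}",
                mate1=m1,
                mate2=m2,
                label=label,
                source_genome=gid,
                position=pos,
            )
        )
    return pairs


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(codes.size) < rate)[0]
    if hit.size:
        lookup = {ord(b): i for i, b in enumerate("ACGT")}
        for i in hit:
            cur = lookup.get(codes[i])
            if cur is None:
                continue
            codes[i] = ord("ACGT"[(cur + 1 + int(rng.integers(0, 3))) % 4])
    return codes.tobytes().decode("ascii")


def two_chain_corpora(
    order: int = 2,
    gc_virus: float = 0.35,
    gc_host: float = 0.65,
    n_genomes: int = 8,
    genome_length: int = 125_000,
    wobble: float = 0.15,
    seed: int = 0,
) -> tuple[list, list, GeneratorSpec, GeneratorSpec]:
    """Standard two-chain benchmark corpora (default 1 Mb per class).

    Returns (virus_genomes, host_genomes, virus_spec, host_spec) where each
    genome list is ``[(id, [sequence]), ...]`` ready for training.  Per-genome
    GC varies by sampling noise, so GC-quantile binning is exercised.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_genomes + 2) & 0x7FFFFFFF
    virus_spec = gc_biased_spec(order, gc_virus, wobble, seed=int(seeds[0]), name="virus")
    host_spec = gc_biased_spec(order, gc_host, wobble, seed=int(seeds[1]), name="host")
    virus_genomes = [
        (f"virus_g{i}", [synthesize_genome(virus_spec, genome_length, seed=int(seeds[2 + i]))])
        for i in range(n_genomes)
    ]
    host_genomes = [
        (
            f"host_g{i}",
            [synthesize_genome(host_spec, genome_length, seed=int(seeds[2 + n_genomes + i]))],
        )
        for i in range(n_genomes)
    ]
    return virus_genomes, host_genomes, virus_spec, host_spec
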