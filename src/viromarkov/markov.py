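"""Strand-symmetric k-mer counting and k-th order Markov chain estimation.

DNA sequence is double stranded, and a training corpus can mix records from
either strand, so every k-mer word ``w`` is counted together with its reverse
complement ``w̄``.  A k-th order chain is then the 4^k x 4 matrix of
conditional probabilities P(x | u) of observing base ``x`` after the context
``u``; sequences are scored by their mean per-window log probability.

Words are held as dense integer-indexed numpy arrays (base A=0, C=1, G=2, T=3,
big-endian within a word), which keeps counting and scoring vectorised up to
the orders used in practice (k <= 12).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "UnscoreableSequenceError",
    "reverse_complement",
    "encode",
    "kmer_index",
    "index_to_kmer",
    "KmerCountTable",
    "count_kmers",
    "MarkovModel",
    "estimate_transitions",
    "loglik_terms",
    "log_likelihood",
]

BASES = "ACGT"

_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")

_STRICT_TABLE = str.maketrans(
    {**_COMPLEMENT, **{k.lower(): v for k, v in _COMPLEMENT.items()}}
)
_LENIENT_TABLE = str.maketrans(
    {
        **_COMPLEMENT,
        **{k.lower(): v for k, v in _COMPLEMENT.items()},
        **{c: "N" for c in _IUPAC_AMBIGUOUS},
        **{c.lower(): "N" for c in _IUPAC_AMBIGUOUS},
    }
)


class UnscoreableSequenceError(ValueError):
    """Raised when a sequence has no (k+1)-window free of ambiguous bases."""


def reverse_complement(seq: str, strict: bool = True) -> str:
    """Reverse complement of ``seq``, uppercased.

    In strict mode (default) any character outside {A,C,G,T} (either case) is
    rejected.  In lenient mode IUPAC ambiguity codes are mapped to ``N``;
    anything else is still rejected.
    """
    table = _STRICT_TABLE if strict else _LENIENT_TABLE
    out = seq.translate(table)
    allowed = set("ACGT") | ({"N"} if not strict else set())
    for i, c in enumerate(out):
        if c not in allowed:
            raise ValueError(
                f"invalid character {seq[i]!r} at position {i}; "
                "expected A/C/G/T" + ("" if strict else " or an IUPAC code")
            )
    return out[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0,C=1,G=2,T=3, other=-1)."""
    try:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise ValueError(f"non-ASCII character in sequence: {exc}") from exc
    return _ENC[raw]


def kmer_index(word: str) -> int:
    """Integer index of a k-mer (big-endian base-4)."""
    codes = encode(word)
    if (codes < 0).any():
        raise ValueError(f"k-mer {word!r} contains a non-ACGT character")
    idx = 0
    for c in codes:
        idx = (idx << 2) | int(c)
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    return "".join(BASES[(idx >> (2 * (k - 1 - j))) & 3] for j in range(k))


def _revcomp_perm(m: int) -> np.ndarray:
    """Permutation p with p[i] = index of the reverse complement of word i."""
    idx = np.arange(4**m, dtype=np.int64)
    out = np.zeros_like(idx)
    for j in range(m):
        digit = (idx >> (2 * (m - 1 - j))) & 3
        out |= (3 - digit) << (2 * j)
    return out


def window_indices(codes: np.ndarray, m: int) -> tuple[np.ndarray, int]:
    """Indices of all valid length-m windows plus the skipped-window count.

    A window is valid iff every base in it is A/C/G/T.  ``m == 0`` yields one
    pseudo-window per position boundary (n+1 of them, all index 0).
    """
    n = codes.size
    if m == 0:
        return np.zeros(n + 1, dtype=np.int64), 0
    if n < m:
        return np.empty(0, dtype=np.int64), 0
    c = codes.astype(np.int64)
    idx = np.zeros(n - m + 1, dtype=np.int64)
    ok = np.ones(n - m + 1, dtype=bool)
    for j in range(m):
        seg = c[j : n - m + 1 + j]
        idx = (idx << 2) | np.where(seg >= 0, seg, 0)
        ok &= seg >= 0
    return idx[ok], int(np.count_nonzero(~ok))


@dataclass
class KmerCountTable:
    """Strand-symmetric word counts for one training corpus.

    ``counts[i]`` is N(w) for the (k+1)-mer with index ``i``; by construction
    N(w) == N(w̄) for every word.  ``context_counts`` holds the analogous
    totals for all k-mer windows of the corpus (for k == 0 this is the number
    of length-0 windows, doubled for the two strands).
    """

    order: int
    counts: np.ndarray
    context_counts: np.ndarray
    n_sequences: int
    n_skipped_windows: int

    def count(self, word: str) -> int:
        if len(word) != self.order + 1:
            raise ValueError(f"expected a {self.order + 1}-mer, got {word!r}")
        return int(self.counts[kmer_index(word)])

    def context_count(self, word: str) -> int:
        if len(word) != self.order:
            raise ValueError(f"expected a {self.order}-mer, got {word!r}")
        return int(self.context_counts[kmer_index(word) if word else 0])


def count_kmers(sequences: Iterable[str], k: int) -> KmerCountTable:
    """Count all (k+1)-mer and k-mer windows of a corpus, plus reverse
    complements.

    Every valid window increments both the observed word and its reverse
    complement (so palindromic words gain 2 per occurrence); windows touching
    a non-ACGT base are skipped and tallied in ``n_skipped_windows``.
    """
    if k < 0:
        raise ValueError("order k must be >= 0")
    m = k + 1
    counts = np.zeros(4**m, dtype=np.int64)
    ctx = np.zeros(4**k, dtype=np.int64)
    skipped = 0
    n_seq = 0
    for seq in sequences:
        n_seq += 1
        codes = encode(seq)
        widx, nskip = window_indices(codes, m)
        skipped += nskip
        if widx.size:
            counts += np.bincount(widx, minlength=4**m)
        cidx, _ = window_indices(codes, k)
        if cidx.size:
            ctx += np.bincount(cidx, minlength=4**k)
    if counts.sum() == 0:
        raise ValueError(
            f"no trainable windows: no sequence has a clean run of {m} ACGT bases"
        )
    counts = counts + counts[_revcomp_perm(m)]
    ctx = ctx + ctx[_revcomp_perm(k)]
    return KmerCountTable(
        order=k,
        counts=counts,
        context_counts=ctx,
        n_sequences=n_seq,
        n_skipped_windows=skipped,
    )


@dataclass
class MarkovModel:
    """A k-th order chain as a dense (4^k, 4) natural-log transition matrix.

    ``normalization_mode`` is "row" (each context row is a proper conditional
    distribution: denominator is the smoothed row sum) or "prefix" (the
    denominator is the smoothed k-mer window count, which differs from the row
    sum only through sequence-boundary windows).
    """

    order: int
    log_transition: np.ndarray
    pseudocount: float
    normalization_mode: str = "row"
    gc_bin: tuple[float, float] | None = None
    training_meta: Mapping | None = None

    def log_p(self, context: str, base: str) -> float:
        u = kmer_index(context) if context else 0
        return float(self.log_transition[u, kmer_index(base)])


def estimate_transitions(
    table: KmerCountTable, pseudocount: float = 1.0, mode: str = "row"
) -> MarkovModel:
    """Estimate P(x|u) = (N(ux)+c) / denom with additive smoothing c.

    Row mode: denom = sum_x' N(ux') + 4c (proper chain for every context,
    seen or not).  Prefix mode: denom = N(u) + 4c with N(u) the k-mer window
    count, the maximum-likelihood form before boundary effects.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0 (zero counts otherwise yield log 0)")
    if mode not in ("row", "prefix"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    k = table.order
    num = table.counts.reshape(4**k, 4).astype(np.float64) + pseudocount
    if mode == "row":
        denom = num.sum(axis=1)
    else:
        denom = table.context_counts.astype(np.float64) + 4.0 * pseudocount
    logp = np.log(num) - np.log(denom)[:, None]
    return MarkovModel(
        order=k,
        log_transition=logp,
        pseudocount=float(pseudocount),
        normalization_mode=mode,
    )


def loglik_terms(seq: str, model: MarkovModel) -> tuple[float, int]:
    """Sum of per-window log transition probabilities and the window count.

    Returns ``(0.0, 0)`` when no window is scoreable; callers decide whether
    that is an error (see :func:`log_likelihood`) or a sentinel state.
    """
    widx, _ = window_indices(encode(seq), model.order + 1)
    if widx.size == 0:
        return 0.0, 0
    lp = model.log_transition[widx >> 2, widx & 3]
    return float(lp.sum()), int(widx.size)


def log_likelihood(seq: str, model: MarkovModel) -> float:
    """Mean log P(base | k preceding bases) over all scoreable windows."""
    total, n = loglik_terms(seq, model)
    if n == 0:
        raise UnscoreableSequenceError(
            f"sequence of length {len(seq)} has no scoreable window at order "
            f"{model.order}"
        )
    return total / n
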