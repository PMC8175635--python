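"""λ likelihood-ratio scores, empirical p-values, q-values and read filtering.

A query is scored against each class by the best mean log-likelihood over
that class's GC-binned chains; λ compares the two.  Mean log-likelihoods are
negative, so the default "decision" orientation puts the host value in the
numerator: λ = LL_host / LL_virus, which makes λ > 1 exactly when the viral
likelihood is the larger one.  λ is a ratio of two mean logs and is therefore
invariant to the logarithm base.

Scores of contigs of different lengths are not directly comparable, so an
empirical p-value is attached: the fraction of held-out bacterial fragments
(the stored null, length-stratified) whose λ exceeds the query's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .markov import encode, window_indices
from .model import Classifier

__all__ = [
    "ScoreRecord",
    "lambda_score",
    "empirical_pvalue",
    "qvalues",
    "score_read_pair",
    "filter_reads",
    "FilterResult",
    "records_to_frame",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = ["id", "length", "ll_virus", "ll_host", "lambda", "pvalue", "qvalue", "call"]


@dataclass
class ScoreRecord:
    """Per-sequence classification record (one TSV row)."""

    id: str
    length: int
    ll_virus: float | None = None
    ll_host: float | None = None
    lambda_: float | None = None
    pvalue: float | None = None
    qvalue: float | None = None
    call: str = "unscoreable"

    def to_row(self) -> list:
        return [
            self.id,
            self.length,
            self.ll_virus,
            self.ll_host,
            self.lambda_,
            self.pvalue,
            self.qvalue,
            self.call,
        ]


def records_to_frame(records: Sequence[ScoreRecord]):
    import pandas as pd

    return pd.DataFrame([r.to_row() for r in records], columns=SCORE_COLUMNS)


def _model_sums(widx: np.ndarray, ensemble) -> np.ndarray:
    """Per-model sums of log transition terms for precomputed window indices."""
    ctx = widx >> 2
    nxt = widx & 3
    return np.array([float(m.log_transition[ctx, nxt].sum()) for m in ensemble.models])


def _lambda_from_lls(ll_virus: float, ll_host: float, orientation: str) -> float:
    if orientation == "literal":
        return ll_virus / ll_host
    return ll_host / ll_virus


def _finish_record(rec: ScoreRecord, classifier: Classifier) -> ScoreRecord:
    rec.call = "viral" if rec.lambda_ > 1.0 else "host"
    null = classifier.null_for_length(rec.length)
    if null is not None:
        rec.pvalue = empirical_pvalue(rec.lambda_, null)
    return rec


def lambda_score(seq: str, classifier: Classifier, seq_id: str = "query") -> ScoreRecord:
    """Score one sequence: component LLs, λ, call and (if available) p-value.

    A sequence with no clean (k+1)-window is returned with
    ``call == "unscoreable"`` rather than an arbitrary score.
    """
    widx, _ = window_indices(encode(seq), classifier.order + 1)
    rec = ScoreRecord(id=seq_id, length=len(seq))
    if widx.size == 0:
        return rec
    n = widx.size
    rec.ll_virus = float(_model_sums(widx, classifier.virus).max() / n)
    rec.ll_host = float(_model_sums(widx, classifier.host).max() / n)
    rec.lambda_ = _lambda_from_lls(rec.ll_virus, rec.ll_host, classifier.orientation)
    return _finish_record(rec, classifier)


def empirical_pvalue(lam: float, null: Sequence[float], smoothing: bool = False) -> float:
    """Fraction of null λ scores strictly greater than ``lam``.

    ``smoothing=True`` uses (count+1)/(n+1), which avoids exact zeros; the
    default is the plain fraction.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("classifier built without null fragments; no p-value available")
    greater = null.size - int(np.searchsorted(null, lam, side="right"))
    if smoothing:
        return (greater + 1) / (null.size + 1)
    return greater / null.size


def qvalues(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """FDR-adjusted q-values (monotone, in [0,1]).

    "bh" is Benjamini–Hochberg; "storey" scales BH by the π0 estimate
    min(1, 2·mean(p > 0.5)).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bh", "storey"):
        raise ValueError(f"unknown q-value method {method!r}")
    from statsmodels.stats.multitest import multipletests

    q = multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, float((p > 0.5).mean()) / 0.5)
        pi0 = max(pi0, 1.0 / p.size)
        q = np.minimum(q * pi0, 1.0)
    return q


def _read_id(read) -> str:
    return read.id if hasattr(read, "id") else read[0]


def _read_seq(read) -> str:
    return read.sequence if hasattr(read, "sequence") else read[1]


def _pair_key(read_id: str) -> str:
    rid = read_id.split()[0] if read_id else read_id
    for suffix in ("/1", "/2", ".1", ".2"):
        if rid.endswith(suffix):
            return rid[: -len(suffix)]
    return rid


def score_read_pair(read1, read2, classifier: Classifier) -> ScoreRecord:
    """Score a mate pair jointly: the mean is taken over the union of both
    mates' scoreable windows (no window spans the mate junction)."""
    s1, s2 = _read_seq(read1), _read_seq(read2)
    w1, _ = window_indices(encode(s1), classifier.order + 1)
    w2, _ = window_indices(encode(s2), classifier.order + 1)
    rec = ScoreRecord(id=_pair_key(_read_id(read1)), length=len(s1) + len(s2))
    n = w1.size + w2.size
    if n == 0:
        return rec
    sums_v = _model_sums(w1, classifier.virus) + _model_sums(w2, classifier.virus)
    sums_h = _model_sums(w1, classifier.host) + _model_sums(w2, classifier.host)
    rec.ll_virus = float(sums_v.max() / n)
    rec.ll_host = float(sums_h.max() / n)
    rec.lambda_ = _lambda_from_lls(rec.ll_virus, rec.ll_host, classifier.orientation)
    return _finish_record(rec, classifier)


@dataclass
class FilterResult:
    """Partitioned read pairs plus the filtering summary.

    Each partition is a list of ``(read1, read2, ScoreRecord)`` in input
    order; ``summary`` reports counts and the realized λ cutoff.
    """

    kept: list
    discarded: list
    unscoreable: list
    summary: dict


def filter_reads(
    pairs: Iterable,
    classifier: Classifier,
    lambda_min: float | None = None,
    top_fraction: float | None = None,
    unscoreable: str = "discard",
) -> FilterResult:
    """Partition mate pairs into kept / discarded / unscoreable streams.

    Exactly one rule must be given: a fixed λ threshold (kept iff
    λ >= lambda_min) or a top fraction f (score everything, then keep the
    floor(f·n) highest-λ pairs, ties broken by pair id).  Mates must be
    synchronized; an id mismatch raises naming the offending record.
    """
    if (lambda_min is None) == (top_fraction is None):
        raise ValueError("give exactly one of lambda_min or top_fraction")
    if top_fraction is not None and not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if unscoreable not in ("discard", "keep"):
        raise ValueError(f"unknown unscoreable policy {unscoreable!r}")

    scored: list = []
    unscored: list = []
    for read1, read2 in pairs:
        id1, id2 = _read_id(read1), _read_id(read2)
        if _pair_key(id1) != _pair_key(id2):
            raise ValueError(f"desynchronized mates: {id1!r} paired with {id2!r}")
        rec = score_read_pair(read1, read2, classifier)
        if rec.call == "unscoreable":
            unscored.append((read1, read2, rec))
        else:
            scored.append((read1, read2, rec))

    if lambda_min is not None:
        cutoff = float(lambda_min)
        kept = [t for t in scored if t[2].lambda_ >= cutoff]
        rule = {"rule": "threshold", "lambda_min": cutoff}
    else:
        n_keep = int(math.floor(top_fraction * len(scored) + 1e-9))
        ranked = sorted(scored, key=lambda t: (-t[2].lambda_, t[2].id))
        keep_ids = {id(t) for t in ranked[:n_keep]}
        kept = [t for t in scored if id(t) in keep_ids]
        cutoff = ranked[n_keep - 1][2].lambda_ if n_keep > 0 else float("inf")
        rule = {"rule": "top_fraction", "top_fraction": float(top_fraction)}
    kept_set = {id(t) for t in kept}
    discarded = [t for t in scored if id(t) not in kept_set]
    if unscoreable == "keep":
        kept = kept + unscored
        unscored_out: list = []
    else:
        unscored_out = unscored
    summary = {
        **rule,
        "n_pairs": len(scored) + len(unscored),
        "n_kept": len(kept),
        "n_discarded": len(discarded),
        "n_unscoreable": len(unscored_out) if unscoreable == "discard" else 0,
        "realized_cutoff": cutoff,
        "fraction_kept": (len(kept) / (len(scored) + len(unscored)))
        if (scored or unscored)
        else 0.0,
        "unscoreable_policy": unscoreable,
    }
    return FilterResult(kept=kept, discarded=discarded, unscoreable=unscored_out, summary=summary)
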