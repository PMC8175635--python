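"""GC-binned Markov-chain ensembles and the two-class likelihood classifier.

Viral and bacterial genomes occupy broad, overlapping ranges of GC content,
and a single chain per class blurs the compositional signal.  Each class is
therefore partitioned into M groups at the empirical quantiles of its own
per-genome GC fraction, and one Markov chain is fitted per group; a query is
scored against a class by the best (largest) mean log-likelihood over that
class's M chains.

The public modelling surface follows the Model/Results convention: build a
:class:`ViralMarkovClassifier` from training genomes, call :meth:`fit`, and
work with the returned :class:`ViralMarkovResults` (scoring, filtering,
summary, persistence).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .markov import (
    MarkovModel,
    count_kmers,
    estimate_transitions,
    loglik_terms,
)

__all__ = [
    "gc_content",
    "assign_gc_bins",
    "ModelEnsemble",
    "train_ensemble",
    "Classifier",
    "build_classifier",
    "null_stratum",
    "save_classifier",
    "load_classifier",
    "ViralMarkovClassifier",
    "ViralMarkovResults",
]

FORMAT_VERSION = 1
_MAGIC = b"VMCENS\x01\n"

Genome = tuple[str, Sequence[str]]


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T) of a sequence; non-ACGT characters are ignored."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("sequence has no A/C/G/T characters; GC content undefined")
    return gc / (gc + at)


def _genome_gc(sequences: Sequence[str]) -> float:
    gc = at = 0
    for seq in sequences:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("genome has no A/C/G/T characters; GC content undefined")
    return gc / (gc + at)


def assign_gc_bins(genome_gcs: Sequence[float], n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign genomes to GC-quantile bins.

    Interior edges sit at the j/M empirical quantiles (j = 1..M-1) of the GC
    values; outer edges are widened to 0 and 1.  A genome exactly on an
    interior edge goes to the lower bin (deterministic tie rule).

    Returns ``(bin_index per genome, edges of length M+1)``.
    """
    gcs = np.asarray(genome_gcs, dtype=float)
    if n_bins < 1:
        raise ValueError("number of bins must be >= 1")
    if gcs.size < n_bins:
        raise ValueError(f"need at least {n_bins} genomes for {n_bins} bins, got {gcs.size}")
    if n_bins == 1:
        return np.zeros(gcs.size, dtype=int), np.array([0.0, 1.0])
    if np.unique(gcs).size < n_bins:
        raise ValueError(
            f"only {np.unique(gcs).size} distinct GC values for {n_bins} bins; "
            "use a smaller number of bins"
        )
    interior = np.quantile(gcs, np.arange(1, n_bins) / n_bins)
    if np.unique(interior).size < n_bins - 1:
        raise ValueError(
            "tied GC quantiles leave an empty bin; use a smaller number of bins"
        )
    bins = np.searchsorted(interior, gcs, side="left")
    occupied = np.bincount(bins, minlength=n_bins)
    if (occupied == 0).any():
        raise ValueError(
            "quantile binning left an empty bin; use a smaller number of bins"
        )
    edges = np.concatenate([[0.0], interior, [1.0]])
    return bins, edges


@dataclass
class ModelEnsemble:
    """One class's M GC-binned chains plus the bin boundaries."""

    class_label: str
    models: list[MarkovModel]
    bin_edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.models)

    @property
    def order(self) -> int:
        return self.models[0].order


def train_ensemble(
    genomes: Iterable[Genome],
    order: int,
    n_bins: int,
    pseudocount: float = 1.0,
    normalization: str = "row",
    class_label: str = "class",
) -> ModelEnsemble:
    """Quantile-bin genomes by GC and fit one chain per bin.

    A genome is ``(id, [record sequences])``; its GC is computed over the
    concatenation of its records, while counting still respects record
    boundaries (no window spans two records).
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError(f"no training genomes for class {class_label!r}")
    gcs = [_genome_gc(seqs) for _, seqs in genomes]
    bins, edges = assign_gc_bins(gcs, n_bins)
    models: list[MarkovModel] = []
    for b in range(n_bins):
        member_idx = [i for i, bi in enumerate(bins) if bi == b]
        pooled: list[str] = []
        for i in member_idx:
            pooled.extend(genomes[i][1])
        table = count_kmers(pooled, order)
        model = estimate_transitions(table, pseudocount=pseudocount, mode=normalization)
        model.gc_bin = (float(edges[b]), float(edges[b + 1]))
        model.training_meta = {
            "class_label": class_label,
            "n_genomes": len(member_idx),
            "n_sequences": table.n_sequences,
        }
        models.append(model)
    return ModelEnsemble(class_label=class_label, models=models, bin_edges=edges)


def null_stratum(length: int, mode: str = "length") -> str:
    """Stratum key for the bacterial null distribution of a given length."""
    if mode == "pooled":
        return "pooled"
    if length < 1:
        raise ValueError("length must be >= 1")
    return f"log2_{int(math.floor(math.log2(length)))}"


@dataclass
class Classifier:
    """Fitted two-class artifact: ensembles, config and the λ null.

    ``null_scores`` maps a length-stratum key to the ascending-sorted λ
    scores of held-out bacterial fragments; a query uses its own stratum,
    falling back to the nearest populated one.
    """

    virus: ModelEnsemble
    host: ModelEnsemble
    null_scores: dict[str, np.ndarray] = field(default_factory=dict)
    order: int = 9
    n_bins: int = 4
    pseudocount: float = 1.0
    normalization: str = "row"
    orientation: str = "decision"
    null_stratification: str = "length"
    format_version: int = FORMAT_VERSION

    def null_for_length(self, length: int) -> np.ndarray | None:
        if not self.null_scores:
            return None
        if self.null_stratification == "pooled":
            return self.null_scores["pooled"]
        want = int(math.floor(math.log2(max(length, 1))))
        have = sorted(int(k.split("_", 1)[1]) for k in self.null_scores)
        best = min(have, key=lambda e: (abs(e - want), e))
        return self.null_scores[f"log2_{best}"]


def build_classifier(
    virus_genomes: Iterable[Genome],
    host_genomes: Iterable[Genome],
    order: int = 9,
    n_bins: int = 4,
    pseudocount: float = 1.0,
    normalization: str = "row",
    orientation: str = "decision",
    null_fragments: Iterable[tuple[str, str]] | None = None,
    null_stratification: str = "length",
) -> Classifier:
    """Train both class ensembles and (optionally) the bacterial λ null.

    Each class is binned at the quantiles of its own GC distribution.  The
    functional twin of ``ViralMarkovClassifier(...).fit(...)``.
    """
    virus = train_ensemble(
        virus_genomes, order, n_bins, pseudocount, normalization, class_label="virus"
    )
    host = train_ensemble(
        host_genomes, order, n_bins, pseudocount, normalization, class_label="host"
    )
    clf = Classifier(
        virus=virus,
        host=host,
        order=order,
        n_bins=n_bins,
        pseudocount=pseudocount,
        normalization=normalization,
        orientation=orientation,
        null_stratification=null_stratification,
    )
    if null_fragments is not None:
        from .scoring import lambda_score

        by_stratum: dict[str, list[float]] = {}
        for frag_id, seq in null_fragments:
            rec = lambda_score(seq, clf, seq_id=frag_id)
            if rec.call == "unscoreable":
                continue
            key = null_stratum(rec.length, null_stratification)
            by_stratum.setdefault(key, []).append(rec.lambda_)
        clf.null_scores = {
            key: np.sort(np.asarray(vals, dtype=float)) for key, vals in by_stratum.items()
        }
    return clf


# ---------------------------------------------------------------------------
# persistence: deterministic single-file container (JSON header + raw arrays)
# ---------------------------------------------------------------------------


def _ensemble_payload(ens: ModelEnsemble, arrays: list[np.ndarray], prefix: str) -> dict:
    entries = []
    for m in ens.models:
        arrays.append(np.ascontiguousarray(m.log_transition, dtype="<f8"))
        entries.append(
            {
                "array": len(arrays) - 1,
                "gc_bin": list(m.gc_bin) if m.gc_bin else None,
                "training_meta": dict(m.training_meta or {}),
            }
        )
    return {
        "class_label": ens.class_label,
        "bin_edges": [float(e) for e in ens.bin_edges],
        "models": entries,
    }


def save_classifier(clf: Classifier, path) -> None:
    """Write a classifier to a versioned single-file container.

    Layout: magic, 8-byte big-endian header length, JSON header, then the raw
    little-endian float64 bytes of every array in manifest order.  The bytes
    are a pure function of the classifier, so identical training inputs give
    byte-identical files.
    """
    arrays: list[np.ndarray] = []
    header = {
        "format_version": clf.format_version,
        "order": clf.order,
        "n_bins": clf.n_bins,
        "pseudocount": clf.pseudocount,
        "normalization": clf.normalization,
        "orientation": clf.orientation,
        "null_stratification": clf.null_stratification,
        "virus": _ensemble_payload(clf.virus, arrays, "virus"),
        "host": _ensemble_payload(clf.host, arrays, "host"),
        "null": {},
    }
    for key in sorted(clf.null_scores):
        arrays.append(np.ascontiguousarray(clf.null_scores[key], dtype="<f8"))
        header["null"][key] = len(arrays) - 1
    header["shapes"] = [list(a.shape) for a in arrays]
    blob = json.dumps(header, sort_keys=True).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(blob).to_bytes(8, "big"))
        fh.write(blob)
        for a in arrays:
            fh.write(a.tobytes())


def _ensemble_from_payload(payload: dict, arrays: list[np.ndarray], clf_cfg: dict) -> ModelEnsemble:
    models = []
    for entry in payload["models"]:
        m = MarkovModel(
            order=clf_cfg["order"],
            log_transition=arrays[entry["array"]],
            pseudocount=clf_cfg["pseudocount"],
            normalization_mode=clf_cfg["normalization"],
            gc_bin=tuple(entry["gc_bin"]) if entry["gc_bin"] else None,
            training_meta=entry["training_meta"],
        )
        models.append(m)
    return ModelEnsemble(
        class_label=payload["class_label"],
        models=models,
        bin_edges=np.asarray(payload["bin_edges"], dtype=float),
    )


def load_classifier(path) -> Classifier:
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError(
                f"{path}: not a recognised model container (bad magic); "
                "re-train with this version of the package"
            )
        hlen = int.from_bytes(fh.read(8), "big")
        header = json.loads(fh.read(hlen).decode("utf-8"))
        if header["format_version"] != FORMAT_VERSION:
            raise ValueError(
                f"{path}: model format version {header['format_version']} is not "
                f"supported by this build (expected {FORMAT_VERSION}); re-train"
            )
        arrays = []
        for shape in header["shapes"]:
            n = int(np.prod(shape)) if shape else 1
            buf = fh.read(8 * n)
            arrays.append(np.frombuffer(buf, dtype="<f8").reshape(shape).copy())
    cfg = {k: header[k] for k in ("order", "pseudocount", "normalization")}
    return Classifier(
        virus=_ensemble_from_payload(header["virus"], arrays, cfg),
        host=_ensemble_from_payload(header["host"], arrays, cfg),
        null_scores={k: arrays[i] for k, i in header["null"].items()},
        order=header["order"],
        n_bins=header["n_bins"],
        pseudocount=header["pseudocount"],
        normalization=header["normalization"],
        orientation=header["orientation"],
        null_stratification=header["null_stratification"],
        format_version=header["format_version"],
    )


# ---------------------------------------------------------------------------
# Model / Results API
# ---------------------------------------------------------------------------


class ViralMarkovClassifier:
    """Two-class Markov-chain likelihood model of viral vs host sequences.

    Parameters
    ----------
    virus_genomes, host_genomes
        Training genomes per class, each ``(id, [record sequences])``.
    order
        Markov order k (context length); default 9.
    n_bins
        Number of GC-quantile bins M per class; default 4.
    pseudocount
        Additive smoothing c per (context, base) cell; default 1.
    normalization
        "row" (proper conditional rows) or "prefix" (k-mer-count denominator).
    orientation
        "decision" (λ = LL_host/LL_virus on negative means, so λ>1 ⇔ viral)
        or "literal" (λ = LL_virus/LL_host).
    null_stratification
        "length" (powers-of-two strata) or "pooled".
    """

    def __init__(
        self,
        virus_genomes: Iterable[Genome],
        host_genomes: Iterable[Genome],
        order: int = 9,
        n_bins: int = 4,
        pseudocount: float = 1.0,
        normalization: str = "row",
        orientation: str = "decision",
        null_stratification: str = "length",
    ):
        if order < 0:
            raise ValueError("order must be >= 0")
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if orientation not in ("decision", "literal"):
            raise ValueError(f"unknown orientation {orientation!r}")
        self.virus_genomes = list(virus_genomes)
        self.host_genomes = list(host_genomes)
        self.order = order
        self.n_bins = n_bins
        self.pseudocount = pseudocount
        self.normalization = normalization
        self.orientation = orientation
        self.null_stratification = null_stratification

    @classmethod
    def from_fasta(cls, virus_path, host_path, **kwargs) -> "ViralMarkovClassifier":
        """Build the model from two (optionally gzipped) FASTA files, one
        genome per record."""
        from .io import read_fasta

        virus = [(rid, [seq]) for rid, seq in read_fasta(virus_path)]
        host = [(rid, [seq]) for rid, seq in read_fasta(host_path)]
        return cls(virus, host, **kwargs)

    def fit(self, null_fragments: Iterable[tuple[str, str]] | None = None) -> "ViralMarkovResults":
        """Train both ensembles (and the λ null, if fragments are given)."""
        clf = build_classifier(
            self.virus_genomes,
            self.host_genomes,
            order=self.order,
            n_bins=self.n_bins,
            pseudocount=self.pseudocount,
            normalization=self.normalization,
            orientation=self.orientation,
            null_fragments=null_fragments,
            null_stratification=self.null_stratification,
        )
        return ViralMarkovResults(self, clf)


class ViralMarkovResults:
    """Fitted classifier: scoring, filtering, summary and persistence."""

    def __init__(self, model: ViralMarkovClassifier | None, classifier: Classifier):
        self.model = model
        self.classifier = classifier

    # -- scoring -----------------------------------------------------------

    def score(self, seq: str, seq_id: str = "query"):
        from .scoring import lambda_score

        return lambda_score(seq, self.classifier, seq_id=seq_id)

    def score_records(self, records: Iterable[tuple[str, str]], add_qvalues: bool = False):
        """Score ``(id, sequence)`` records into a DataFrame (input order)."""
        from .scoring import records_to_frame, lambda_score, qvalues

        recs = [lambda_score(seq, self.classifier, seq_id=rid) for rid, seq in records]
        if add_qvalues:
            scored = [r for r in recs if r.pvalue is not None]
            if scored:
                qs = qvalues([r.pvalue for r in scored])
                for r, q in zip(scored, qs):
                    r.qvalue = float(q)
        return records_to_frame(recs)

    def score_pair(self, read1, read2):
        from .scoring import score_read_pair

        return score_read_pair(read1, read2, self.classifier)

    def filter_pairs(self, pairs, lambda_min=None, top_fraction=None, unscoreable="discard"):
        from .scoring import filter_reads

        return filter_reads(
            pairs,
            self.classifier,
            lambda_min=lambda_min,
            top_fraction=top_fraction,
            unscoreable=unscoreable,
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        clf = self.classifier
        buf = io.StringIO()
        w = buf.write
        w("Viral/host Markov-chain likelihood classifier\n")
        w("=" * 54 + "\n")
        w(f"Markov order (k):        {clf.order}\n")
        w(f"GC-quantile bins (M):    {clf.n_bins}\n")
        w(f"Pseudocount (c):         {clf.pseudocount}\n")
        w(f"Normalization:           {clf.normalization}\n")
        w(f"Lambda orientation:      {clf.orientation}\n")
        for ens in (clf.virus, clf.host):
            w(f"\n{ens.class_label} ensemble ({ens.n_bins} bins)\n")
            w(f"{'bin':>4} {'gc_low':>8} {'gc_high':>8} {'genomes':>8} {'records':>8}\n")
            for b, m in enumerate(ens.models):
                meta = m.training_meta or {}
                lo, hi = m.gc_bin or (float("nan"), float("nan"))
                w(
                    f"{b:>4} {lo:>8.4f} {hi:>8.4f} "
                    f"{meta.get('n_genomes', 0):>8} {meta.get('n_sequences', 0):>8}\n"
                )
        if clf.null_scores:
            w("\nBacterial null strata\n")
            for key in sorted(clf.null_scores):
                w(f"  {key}: n={clf.null_scores[key].size}\n")
        else:
            w("\nNo bacterial null stored (p-values unavailable).\n")
        return buf.getvalue()

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        save_classifier(self.classifier, path)

    @classmethod
    def load(cls, path) -> "ViralMarkovResults":
        return cls(None, load_classifier(path))
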