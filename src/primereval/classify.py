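"""Naive-Bayes k-mer taxonomic classifier with bootstrap confidence, plus
SR-vs-NFL assignment-performance scoring.

Scoring follows the Wang-style word model: word prior
P_i = (n(w_i) + 0.5) / (N + 1) over N training sequences, genus conditional
P(w_i|G) = (m(w_i) + P_i) / (M + 1) over the M sequences of genus G; a
query's genus score is the sum of log conditionals over its distinct words.
Bootstrap rounds resample floor(W/8) of the query's W distinct words.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RANKS, SequenceLibrary, get_logger

__all__ = ["ClassifierModel", "ClassificationResult", "train", "classify",
           "classify_library", "score_assignments"]

log = get_logger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _words(seq: str, k: int) -> np.ndarray:
    """Sorted distinct k-mer codes (A/C/G/T only windows)."""
    vals = np.full(len(seq), -1, dtype=np.int64)
    for i, ch in enumerate(seq):
        vals[i] = _CODE.get(ch, -1)
    if len(seq) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    ok = (win >= 0).all(axis=1)
    if not ok.any():
        return np.empty(0, dtype=np.int64)
    mult = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return np.unique(win[ok] @ mult)


@dataclass
class ClassifierModel:
    k: int
    genera: list[str]                      # sorted genus names
    lineages: dict[str, list[tuple[str, str]]]
    log_cond: np.ndarray                   # (n_genera, n_words_in_vocab)
    vocab: np.ndarray                      # sorted word codes
    n_sequences: int = 0
    seq_counts: dict[str, int] = field(default_factory=dict)


def train(reference_library: SequenceLibrary, k: int = 8) -> ClassifierModel:
    """Fit word priors and per-genus conditionals from a labeled library."""
    if k < 1:
        raise ValueError("k must be >= 1")
    by_genus: dict[str, list[np.ndarray]] = {}
    lineages: dict[str, list[tuple[str, str]]] = {}
    for rec in reference_library:
        genus = rec.rank_label("genus")
        if genus is None:
            raise ValueError(f"sequence {rec.id!r} lacks a genus label")
        seq = rec.ungapped
        if len(seq) < k:
            log.warning("skipping %s: shorter than k=%d", rec.id, k)
            continue
        if genus in lineages and lineages[genus] != rec.taxonomy:
            raise ValueError(f"genus {genus!r} maps to multiple lineages")
        lineages[genus] = rec.taxonomy
        by_genus.setdefault(genus, []).append(_words(seq, k))
    if not by_genus:
        raise ValueError("no trainable sequences")
    genera = sorted(by_genus)
    all_words = np.unique(np.concatenate(
        [w for ws in by_genus.values() for w in ws]))
    word_pos = {int(w): i for i, w in enumerate(all_words)}
    V = len(all_words)
    n_total = sum(len(ws) for ws in by_genus.values())
    n_with = np.zeros(V)
    m = np.zeros((len(genera), V))
    for g, genus in enumerate(genera):
        for words in by_genus[genus]:
            idx = np.array([word_pos[int(w)] for w in words], dtype=int)
            n_with[idx] += 1
            m[g, idx] += 1
    prior = (n_with + 0.5) / (n_total + 1)
    sizes = np.array([len(by_genus[g]) for g in genera])[:, None]
    log_cond = np.log((m + prior[None, :]) / (sizes + 1))
    return ClassifierModel(
        k=k, genera=genera, lineages=lineages, log_cond=log_cond,
        vocab=all_words, n_sequences=n_total,
        seq_counts={g: len(by_genus[g]) for g in genera})


@dataclass
class ClassificationResult:
    """Per-rank label (or 'unclassified') with bootstrap confidence 0-100."""

    labels: dict[str, str]
    confidences: dict[str, float]

    def label(self, rank: str) -> str:
        return self.labels.get(rank, "unclassified")

    def confidence(self, rank: str) -> float:
        return self.confidences.get(rank, 0.0)

    def is_classified(self, rank: str) -> bool:
        return self.label(rank) != "unclassified"


_CLASSIFY_RANKS = tuple(r for r in RANKS if r != "domain")


def classify(model: ClassifierModel, query: str, n_bootstrap: int = 100,
             cutoff: float = 80.0, seed: int = 0) -> ClassificationResult:
    """Classify one ungapped sequence; labels below the cutoff fall back to
    'unclassified'.

    The winning genus is the best scorer on the full word set; per rank,
    confidence is the percentage of bootstrap rounds whose winning genus
    shares that rank's label, so labels nest by construction.
    """
    if "-" in query:
        raise ValueError("query must be ungapped")
    if len(query) < model.k:
        raise ValueError("query shorter than k")
    words = _words(query.upper().replace("U", "T"), model.k)
    idx = np.searchsorted(model.vocab, words)
    idx = idx[(idx < len(model.vocab)) & (model.vocab[
        np.minimum(idx, len(model.vocab) - 1)] == words)]
    if idx.size == 0:
        return ClassificationResult(
            {r: "unclassified" for r in _CLASSIFY_RANKS},
            {r: 0.0 for r in _CLASSIFY_RANKS})
    scores = model.log_cond[:, idx].sum(axis=1)
    winner = int(np.argmax(scores))  # genera sorted: ties -> smallest name
    lineage = dict(model.lineages[model.genera[winner]])
    rng = np.random.default_rng(seed)
    n_draw = max(len(idx) // 8, 1)
    wins = np.zeros(len(model.genera), dtype=int)
    for _ in range(n_bootstrap):
        sample = rng.choice(idx, size=n_draw, replace=True)
        wins[int(np.argmax(model.log_cond[:, sample].sum(axis=1)))] += 1
    labels, confidences = {}, {}
    for rank in _CLASSIFY_RANKS:
        target = lineage.get(rank)
        if target is None:
            labels[rank] = "unclassified"
            confidences[rank] = 0.0
            continue
        agree = sum(
            wins[g] for g, genus in enumerate(model.genera)
            if dict(model.lineages[genus]).get(rank) == target)
        conf = 100.0 * agree / n_bootstrap
        confidences[rank] = conf
        labels[rank] = target if conf >= cutoff else "unclassified"
    return ClassificationResult(labels, confidences)


def classify_library(model: ClassifierModel, library: SequenceLibrary,
                     n_bootstrap: int = 100, cutoff: float = 80.0,
                     seed: int = 0) -> dict[str, ClassificationResult]:
    """Classify every record (on its ungapped bases); per-record seeds are
    derived deterministically from the master seed and the record id."""
    import zlib
    out = {}
    for rec in library:
        rec_seed = (seed * 1_000_003 + zlib.crc32(rec.id.encode())) \
            % (2 ** 31)
        out[rec.id] = classify(model, rec.ungapped, n_bootstrap=n_bootstrap,
                               cutoff=cutoff, seed=rec_seed)
    return out


def score_assignments(
    sr_results: dict[str, ClassificationResult],
    nfl_results: dict[str, ClassificationResult],
    rank: str,
    count_both_unclassified: bool = True,
) -> dict[str, float]:
    """SR-vs-NFL agreement percentages at one rank.

    correct_incl counts reads whose SR label equals the NFL label over all
    reads (both-unclassified counts as agreement when
    ``count_both_unclassified``); correct_excl excludes reads unclassified
    in NFL. false_positive: classified in SR, unclassified in NFL.
    false_negative: classified in NFL, unclassified in SR.
    """
    if set(sr_results) != set(nfl_results):
        raise ValueError("SR and NFL result sets cover different reads")
    ids = sorted(sr_results)
    n = len(ids)
    agree = agree_excl = n_excl = fp = fn = un_sr = un_nfl = 0
    for read in ids:
        sr, nfl = sr_results[read], nfl_results[read]
        s_lab, n_lab = sr.label(rank), nfl.label(rank)
        s_cls, n_cls = sr.is_classified(rank), nfl.is_classified(rank)
        same = s_lab == n_lab if (s_cls or n_cls or
                                  count_both_unclassified) else False
        agree += same
        if n_cls:
            n_excl += 1
            agree_excl += s_lab == n_lab
        fp += s_cls and not n_cls
        fn += n_cls and not s_cls
        un_sr += not s_cls
        un_nfl += not n_cls

    def pct(v, d=n):
        return 100.0 * v / d if d else float("nan")

    return {
        "rank": rank,
        "correct_incl": pct(agree),
        "correct_excl": pct(agree_excl, n_excl),
        "false_positive": pct(fp),
        "unclassified_total": pct(un_sr),
        "false_negative": pct(fn),
        "unclassified_ref": pct(un_nfl),
    }


def performance_report(sr_results, nfl_results,
                       ranks=("phylum", "genus")) -> pd.DataFrame:
    rows = [score_assignments(sr_results, nfl_results, rank)
            for rank in ranks]
    return pd.DataFrame(rows)
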