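"""Interpretation of model predictions: threshold choice, confusion
partition, explicit-keyword search and class-characteristic TF-IDF words.

The threshold is the ROC point maximizing TPR/FPR (points with FPR = 0 are
excluded — their ratio is infinite and uninformative — and flagged).  Test
users are partitioned into TP/FP/TN/FN at that threshold; the keyword search
looks for fixed morphological variants of explicit suicide-related lemmas
with word boundaries; TF-IDF concatenates each confusion class into one
document and ranks words by tf * log(N_docs / df) after stop-word removal.
"""

from __future__ import annotations

import dataclasses
import re
from collections import Counter

import numpy as np

from ._lexicons import KEYWORD_VARIANTS
from .embedding import tokenize
from .evaluation import RocCurve

__all__ = [
    "STOP_WORDS", "select_threshold", "ConfusionPartition",
    "partition_confusion", "KeywordMatch", "keyword_search",
    "TfidfReport", "tfidf_class_words",
]

#: compact English stop-word list applied before TF-IDF ranking
STOP_WORDS = frozenset("""
a about above after again all am an and any are as at be because been before
being below between both but by could did do does doing down during each few
for from further had has have having he her here hers herself him himself his
how i if in into is it its itself just me more most my myself no nor not now
of off on once only or other our ours ourselves out over own same she should
so some such than that the their theirs them themselves then there these they
this those through to too under until up very was we were what when where
which while who whom why will with you your yours yourself yourselves
""".split())


# ---------------------------------------------------------------------------
# Threshold and confusion partition
# ---------------------------------------------------------------------------

def select_threshold(roc: RocCurve) -> tuple[float, dict]:
    """Threshold maximizing TPR/FPR over ROC points with FPR > 0.

    Ties break toward higher TPR, then higher threshold.  Returns the
    threshold and a small report (chosen point, number of FPR = 0 points
    excluded)."""
    fpr, tpr, thr = roc.fpr, roc.tpr, roc.thresholds
    usable = (fpr > 0) & (tpr > 0)
    if not usable.any():
        raise ValueError("no ROC point with TPR > 0 and FPR > 0")
    ratio = np.where(usable, tpr / np.where(fpr > 0, fpr, np.inf), -np.inf)
    order = np.lexsort((thr, tpr, ratio))     # last key dominates
    best = order[-1]
    report = {"tpr": float(tpr[best]), "fpr": float(fpr[best]),
              "ratio": float(ratio[best]),
              "n_zero_fpr_excluded": int(((fpr == 0) & (tpr > 0)).sum())}
    return float(thr[best]), report


@dataclasses.dataclass
class ConfusionPartition:
    threshold: float
    tp: list[str]
    fp: list[str]
    tn: list[str]
    fn: list[str]

    def classes(self) -> dict[str, list[str]]:
        return {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn}

    @property
    def tpr(self) -> float:
        return len(self.tp) / max(len(self.tp) + len(self.fn), 1)

    @property
    def fpr(self) -> float:
        return len(self.fp) / max(len(self.fp) + len(self.tn), 1)


def partition_confusion(user_ids: list[str], scores: np.ndarray,
                        labels: np.ndarray, threshold: float
                        ) -> ConfusionPartition:
    """Predicted-positive iff score >= threshold; four disjoint user sets."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(bool).ravel()
    pred = scores >= threshold
    groups: dict[str, list[str]] = {"TP": [], "FP": [], "TN": [], "FN": []}
    for uid, p, y in zip(user_ids, pred, labels):
        key = ("T" if p == y else "F") + ("P" if p else "N")
        groups[key].append(uid)
    return ConfusionPartition(threshold=float(threshold), tp=groups["TP"],
                              fp=groups["FP"], tn=groups["TN"],
                              fn=groups["FN"])


# ---------------------------------------------------------------------------
# Keyword search
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KeywordMatch:
    user_id: str
    post_id: str
    lemma: str
    variant: str
    excerpt: str


def keyword_search(posts_by_user: dict[str, list[str]],
                   lemma_variants: dict[str, tuple[str, ...]] | None = None
                   ) -> list[KeywordMatch]:
    """Case-insensitive, word-boundary search for fixed morphological
    variants of explicit lemmas (default: suicide, kill, die).  One match is
    reported per (post, lemma) with the containing post as excerpt."""
    lemma_variants = lemma_variants or KEYWORD_VARIANTS
    patterns = {
        lemma: re.compile(
            r"\b(" + "|".join(map(re.escape, variants)) + r")\b",
            re.IGNORECASE)
        for lemma, variants in lemma_variants.items()}
    matches: list[KeywordMatch] = []
    for uid in sorted(posts_by_user):
        for j, text in enumerate(posts_by_user[uid]):
            for lemma, pat in patterns.items():
                m = pat.search(text)
                if m:
                    matches.append(KeywordMatch(
                        user_id=uid, post_id=f"{uid}-p{j}", lemma=lemma,
                        variant=m.group(1).lower(), excerpt=text))
    return matches


# ---------------------------------------------------------------------------
# TF-IDF class words
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TfidfReport:
    top_words: dict[str, list[tuple[str, float]]]   # class -> ranked (w, s)

    def words(self, cls: str) -> list[str]:
        return [w for w, _ in self.top_words[cls]]


def tfidf_class_words(posts_by_class: dict[str, list[str]], k: int = 100,
                      per_user_documents: bool = False,
                      documents_by_class: dict[str, list[list[str]]] | None
                      = None) -> TfidfReport:
    """Most characteristic words per confusion class.

    Default document unit: each class's posts concatenated into a single
    document, corpus = the class documents, score = tf * log(N_docs / df).
    Words occurring in every class document get score 0 and are dropped.
    With ``per_user_documents=True`` (requires ``documents_by_class``
    mapping class -> list of per-user post lists) idf is computed over
    user-level documents instead, which keeps ubiquitous words rankable.
    """
    classes = {c: p for c, p in posts_by_class.items() if p}
    if len(classes) < 2:
        raise ValueError("need at least 2 non-empty classes")

    def doc_tokens(posts: list[str]) -> list[str]:
        return [t for post in posts for t in tokenize(post)
                if t not in STOP_WORDS and t.isalpha()]

    tf = {c: Counter(doc_tokens(p)) for c, p in classes.items()}
    if any(not counts for counts in tf.values()):
        raise ValueError("a class document is empty after stop-word removal")

    if per_user_documents:
        if documents_by_class is None:
            raise ValueError(
                "per_user_documents requires documents_by_class")
        docs = [set(doc_tokens(user_posts))
                for users in documents_by_class.values()
                for user_posts in users]
    else:
        docs = [set(counts) for counts in tf.values()]
    n_docs = len(docs)
    df = Counter(w for d in docs for w in d)

    top: dict[str, list[tuple[str, float]]] = {}
    for c, counts in tf.items():
        scored = []
        for w, f in counts.items():
            idf = np.log(n_docs / df[w]) if df[w] else 0.0
            if idf > 0.0:
                scored.append((w, float(f * idf)))
        scored.sort(key=lambda ws: (-ws[1], ws[0]))
        top[c] = scored[:k]
    return TfidfReport(top_words=top)
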