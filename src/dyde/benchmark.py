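"""Link-recovery evaluation against a ground-truth adjacency (AUROC / AUPR)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = ["EdgeScores", "auroc", "aupr", "score_links"]


@dataclass(frozen=True)
class EdgeScores:
    """Confidence scores and truth labels for directed non-self gene pairs."""

    pairs: tuple[tuple[str, str], ...]
    scores: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        truth = np.asarray(self.truth, dtype=bool)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "truth", truth)
        if not (len(self.pairs) == scores.size == truth.size):
            raise ValueError("pairs, scores and truth must align")
        for s, t in self.pairs:
            if s == t:
                raise ValueError(f"self pair {s}->{t} not allowed")


def score_links(links, reference: Sequence[tuple[str, str]]) -> EdgeScores:
    """Build EdgeScores from fitted links: score = fitness, truth from reference.

    With links from several conditions for the same pair, the maximum
    fitness is used as the pair's confidence.
    """
    ref = {tuple(e) for e in reference}
    best: dict[tuple[str, str], float] = {}
    for l in links:
        f = l.model.fitness_pct
        if f is None:
            continue
        best[l.key] = max(best.get(l.key, -np.inf), f)
    pairs = tuple(sorted(best))
    return EdgeScores(
        pairs=pairs,
        scores=np.array([best[p] for p in pairs]),
        truth=np.array([p in ref for p in pairs]),
    )


def auroc(scores: EdgeScores) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties give 0.5."""
    y = scores.truth
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(scores.scores)  # average ranks on ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aupr(scores: EdgeScores) -> float:
    """Area under the precision-recall curve by step-wise summation.

    Pairs are taken in descending score order with equal scores grouped;
    the area is the sum over groups of (recall increment) x (precision at
    the group boundary), i.e. average precision without interpolation.
    """
    y = scores.truth.astype(float)
    n_pos = y.sum()
    if n_pos == 0:
        raise ValueError("AUPR requires at least one positive")
    order = np.argsort(-scores.scores, kind="stable")
    s_sorted = scores.scores[order]
    y_sorted = y[order]
    # group boundaries: last index of each run of equal scores
    boundaries = np.where(np.diff(s_sorted) != 0)[0]
    ends = np.concatenate([boundaries, [s_sorted.size - 1]])
    tp = np.cumsum(y_sorted)[ends]
    n_seen = ends + 1.0
    precision = tp / n_seen
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))
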