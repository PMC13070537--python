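"""Complex-matching metrics and rank statistics.

Predicted complexes are matched to a reference catalogue through the
neighborhood affinity score OS(p, g) = |p∩g|²/(|p|·|g|); a pair matches when
OS ≥ δ. From the match sets come precision, recall and F-measure; from the
shared-protein counts T_ij come sensitivity Sn, positive predictive value PPV
and their geometric mean ACC; F1+ACC = F-measure + ACC is the composite index.

For comparing a algorithms over s datasets, the Friedman chi-square test on
average ranks (χ² = 12s/(a(a+1))·Σr̄² − 3s(a+1), df = a−1) assesses overall
differences, and the Nemenyi critical difference CD = q_α·√(a(a+1)/(6s))
marks the minimum significant rank gap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ppi_io import ComplexSet

logger = logging.getLogger(__name__)

__all__ = [
    "MatchReport",
    "RankTable",
    "overlap_score",
    "precision_recall_f",
    "sn_ppv_acc",
    "match_report",
    "friedman_test",
    "nemenyi_cd",
    "rank_scores",
]


@dataclass
class MatchReport:
    delta: float
    precision: float
    recall: float
    f_measure: float
    sn: float
    ppv: float
    acc: float
    f1_plus_acc: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RankTable:
    """Average ranks r̄_j of a algorithms over s datasets (rank 1 = best)."""

    algorithms: list[str]
    avg_ranks: np.ndarray
    n_datasets: int

    @property
    def n_algorithms(self) -> int:
        return len(self.algorithms)


def overlap_score(pc: frozenset | set, gc: frozenset | set) -> float:
    """Neighborhood affinity OS = |pc∩gc|² / (|pc|·|gc|)."""
    if not pc or not gc:
        raise ValueError("overlap score needs non-empty sets")
    inter = len(set(pc) & set(gc))
    return inter * inter / (len(pc) * len(gc))


def precision_recall_f(pred: ComplexSet, ref: ComplexSet,
                       delta: float = 0.25) -> tuple[float, float, float]:
    """Fraction of predictions matched (precision), references matched
    (recall), and their harmonic mean, at OS threshold δ."""
    if len(pred) == 0 or len(ref) == 0:
        raise ValueError("both complex sets must be non-empty")
    if not 0 < delta <= 1:
        raise ValueError("delta must lie in (0, 1]")
    matched_pred = sum(
        1 for p in pred if any(overlap_score(p, g) >= delta for g in ref))
    matched_ref = sum(
        1 for g in ref if any(overlap_score(p, g) >= delta for p in pred))
    precision = matched_pred / len(pred)
    recall = matched_ref / len(ref)
    f = (2 * precision * recall / (precision + recall)
         if precision + recall > 0 else 0.0)
    return precision, recall, f


def sn_ppv_acc(pred: ComplexSet, ref: ComplexSet) -> tuple[float, float, float]:
    """Sensitivity, PPV and their geometric mean over shared-protein counts.

    T_ij = |g_i ∩ p_j|; Sn = Σ_i max_j T_ij / Σ_i |g_i|;
    PPV = Σ_j max_i T_ij / Σ_j Σ_i T_ij; ACC = √(Sn·PPV).
    """
    if len(pred) == 0 or len(ref) == 0:
        raise ValueError("both complex sets must be non-empty")
    T = np.array([[len(g & p) for p in pred] for g in ref], dtype=float)
    sn = float(T.max(axis=1).sum() / sum(len(g) for g in ref))
    col_tot = T.sum(axis=0)
    ppv = float(T.max(axis=0).sum() / col_tot.sum()) if col_tot.sum() > 0 else 0.0
    return sn, ppv, math.sqrt(sn * ppv)


def match_report(pred: ComplexSet, ref: ComplexSet, delta: float = 0.25) -> MatchReport:
    """All matching metrics in one pass."""
    p, r, f = precision_recall_f(pred, ref, delta)
    sn, ppv, acc = sn_ppv_acc(pred, ref)
    return MatchReport(delta=delta, precision=p, recall=r, f_measure=f,
                       sn=sn, ppv=ppv, acc=acc, f1_plus_acc=f + acc)


def rank_scores(scores: np.ndarray) -> np.ndarray:
    """Average ranks from a (algorithms × datasets) score matrix; higher score
    is better (rank 1), ties get average ranks."""
    scores = np.asarray(scores, dtype=float)
    ranks = np.empty_like(scores)
    for j in range(scores.shape[1]):
        ranks[:, j] = stats.rankdata(-scores[:, j], method="average")
    return ranks.mean(axis=1)


def friedman_test(table: RankTable, variant: str = "chi-square") -> tuple[float, float]:
    """Friedman test on average ranks.

    Default is the chi-square form with df = a−1; ``variant="iman-davenport"``
    applies the F-distribution correction F = (s−1)χ² / (s(a−1) − χ²).
    A rank-sum deviation beyond 0.5 from a(a+1)/2 is logged, not fatal.
    """
    a, s = table.n_algorithms, table.n_datasets
    if a < 3 or s < 2:
        raise ValueError("need at least 3 algorithms and 2 datasets")
    r = np.asarray(table.avg_ranks, dtype=float)
    expected = a * (a + 1) / 2
    if abs(r.sum() - expected) > 0.5:
        logger.warning("average ranks sum to %.1f, expected %.1f",
                       r.sum(), expected)
    chi2 = 12.0 * s / (a * (a + 1)) * float((r ** 2).sum()) - 3.0 * s * (a + 1)
    if variant == "chi-square":
        p = float(stats.chi2.sf(chi2, a - 1))
        return chi2, p
    if variant == "iman-davenport":
        ff = (s - 1) * chi2 / (s * (a - 1) - chi2)
        p = float(stats.f.sf(ff, a - 1, (a - 1) * (s - 1)))
        return ff, p
    raise ValueError(f"unknown variant: {variant!r}")


def nemenyi_cd(a: int, s: int, q_alpha: float) -> float:
    """Critical difference CD = q_α·√(a(a+1)/(6s))."""
    if a < 2 or s < 1 or q_alpha <= 0:
        raise ValueError("need a >= 2, s >= 1, q_alpha > 0")
    return q_alpha * math.sqrt(a * (a + 1) / (6.0 * s))
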