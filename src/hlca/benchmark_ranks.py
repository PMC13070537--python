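"""Published average ranks of 14 protein-complex detection algorithms.

Average ranks over the five yeast PPI datasets (Gavin1, Gavin2, K_extend,
DIP, BioGRID), under the CYC2008 and MIPS reference catalogues, for three
metrics (F-measure, Accuracy, F1+ACC). Rank 1 is best; with a = 14
algorithms and s = 5 datasets the ranks of each row should sum to
a(a+1)/2 = 105. The CYC2008 F1+ACC row as published sums to 103.8 — it is
kept verbatim here and flagged, not corrected.

These tables are the input to the rank-statistics suite (Friedman test and
Nemenyi critical difference with q_0.1 = 2.978).
"""

from __future__ import annotations

import numpy as np

from .evaluate import RankTable

__all__ = ["ALGORITHMS", "N_DATASETS", "Q_ALPHA_01", "BENCHMARK_RANKS",
           "benchmark_table"]

ALGORITHMS = [
    "DPClus", "IPCA", "CORE", "SR-MCL", "SEGC", "DCU", "COACH", "WCOACH",
    "CFinder", "GCAPL", "DMPC", "BOPS", "DPCMNE", "HLCA",
]

N_DATASETS = 5
Q_ALPHA_01 = 2.978  # studentized-range constant for 14 groups at alpha = 0.1

BENCHMARK_RANKS: dict[str, list[float]] = {
    "cyc2008_f_measure": [7.4, 5.8, 10.2, 8, 5, 12.8, 9, 13.4, 12, 2.6, 6, 6.4, 3.6, 2.8],
    "cyc2008_accuracy":  [4.6, 6.2, 4.4, 8.2, 3.6, 9.6, 13.4, 11.8, 11.6, 2.6, 7.4, 11.2, 9.2, 1.2],
    # published row; sums to 103.8 rather than 105 (kept verbatim)
    "cyc2008_f1_plus_acc": [6.6, 5, 8.8, 7.4, 4.2, 11.4, 12.4, 13.2, 12, 2.2, 5, 8.8, 5.6, 1.2],
    "mips_f_measure":    [7.8, 6.4, 10, 6.4, 5.6, 13.6, 11.6, 12.4, 11.4, 2.8, 4.8, 7, 1.8, 3.4],
    "mips_accuracy":     [6, 4.2, 5.2, 7.2, 2.2, 8.8, 13, 11.2, 12, 2.8, 8.6, 10, 12.6, 1.2],
    "mips_f1_plus_acc":  [7.8, 5.2, 8.4, 6.4, 3.8, 11.8, 13.4, 12.4, 12, 2, 6, 9.2, 5.6, 1],
}


def benchmark_table(key: str) -> RankTable:
    """RankTable for one published metric row, e.g. ``"mips_f_measure"``."""
    return RankTable(algorithms=list(ALGORITHMS),
                     avg_ranks=np.array(BENCHMARK_RANKS[key], dtype=float),
                     n_datasets=N_DATASETS)
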