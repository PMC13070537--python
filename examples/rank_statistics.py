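"""Friedman test and Nemenyi critical difference on published rank tables.

The package ships the average ranks of 14 complex-detection algorithms over
five yeast PPI datasets (two reference catalogues x three metrics). The
Friedman chi-square test asks whether the algorithms differ at all; the
Nemenyi critical difference is the minimum average-rank gap that is
significant at alpha = 0.1.
"""

from hlca.benchmark_ranks import (ALGORITHMS, BENCHMARK_RANKS, N_DATASETS,
                                  Q_ALPHA_01, benchmark_table)
from hlca.evaluate import friedman_test, nemenyi_cd

a = len(ALGORITHMS)
cd = nemenyi_cd(a, N_DATASETS, Q_ALPHA_01)
print(f"{a} algorithms over {N_DATASETS} datasets: CD = {cd:.2f}")

for key in BENCHMARK_RANKS:
    chi2, p = friedman_test(benchmark_table(key))
    print(f"{key:24s} chi2 = {chi2:6.2f}  p = {p:.3e}")
# p-values far below 0.05 mean the rank differences across algorithms are
# statistically significant; any pair of algorithms whose average ranks
# differ by at least CD differs significantly under the Nemenyi test.
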