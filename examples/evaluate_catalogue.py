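"""Score a predicted complex catalogue against a reference catalogue.

Writes two small catalogues to disk (the usual one-complex-per-line text
format), reads them back, and prints every matching metric.
"""

import tempfile
from pathlib import Path

from hlca.evaluate import match_report, overlap_score
from hlca.ppi_io import ComplexSet, read_complexes, write_complexes

tmp = Path(tempfile.mkdtemp())
pred = ComplexSet([frozenset({"YAL001C", "YBR123W", "YCR042C"}),
                   frozenset({"YDL005C", "YDR145W", "YEL055C", "YFL039C"}),
                   frozenset({"YGL112C", "YGR274C", "YHR099W"})])
ref = ComplexSet([frozenset({"YAL001C", "YBR123W", "YCR042C", "YPR086W"}),
                  frozenset({"YDL005C", "YDR145W", "YEL055C", "YFL039C"})])
write_complexes(pred, tmp / "pred.txt")
write_complexes(ref, tmp / "ref.txt")

pred2, ref2 = read_complexes(tmp / "pred.txt"), read_complexes(tmp / "ref.txt")
os_val = overlap_score(pred2.complexes[0], ref2.complexes[0])
print(f"OS(first prediction, first reference) = {os_val:.3f}")

mr = match_report(pred2, ref2, delta=0.25)
for k, v in mr.to_dict().items():
    print(f"{k:12s} = {v:.3f}")
# Two of three predictions match a reference at OS >= 0.25 (precision 2/3);
# both references are recovered (recall 1); the unmatched third prediction
# also drags PPV below 1.
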