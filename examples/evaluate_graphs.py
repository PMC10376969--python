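"""Score predicted directed networks against a ground truth.

Walks through the arc taxonomy on a small worked example — correct (CA),
extra (EA), missing (MA) and reversed (RA) arcs — then the derived scores:
precision = CA/TA, recall = CA/|G|, their harmonic mean F1, and the
structural Hamming distance SHD = EA + MA + RA.  Ends with a consensus
network across subjects, keeping arcs present in at least 40% of them.
"""

import numpy as np

import effconn as ec

truth = np.zeros((4, 4), dtype=int)
truth[1, 2] = truth[2, 3] = 1  # arcs 1->2 and 2->3

pred = np.zeros((4, 4), dtype=int)
pred[2, 1] = pred[2, 3] = pred[1, 3] = 1  # 2->1 (reversed), 2->3 (correct), 1->3 (extra)

counts = ec.classify_arcs(pred, truth)
print(f"CA={counts.ca} EA={counts.ea} MA={counts.ma} RA={counts.ra} "
      f"TA={counts.ta} |G|={counts.truth_size}")

report = ec.compute_metrics(counts)
print(f"precision={report.precision:.4f} recall={report.recall:.4f} "
      f"f1={report.f1:.4f} shd={report.shd}")
print("the reversed 2->1 costs one SHD unit but excuses 1->2 from being missing.")

# consensus across a cohort: arcs in >= 40% of subjects survive
rng = np.random.default_rng(0)
subject_graphs = []
for _ in range(23):
    g = truth.copy()
    flip = rng.random(g.shape) < 0.3
    np.fill_diagonal(flip, False)
    g[flip] = 1 - g[flip]
    subject_graphs.append(g)
consensus = ec.edge_frequency(subject_graphs, min_fraction=0.4)
print(f"consensus arcs over 23 noisy subject graphs (>= 10 occurrences): "
      f"{[(int(i), int(j)) for i, j in np.argwhere(consensus == 1)]}")
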