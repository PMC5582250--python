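"""Build a neighbor-joining tree of a synthetic precursor family.

Members of one family are progressively diverged copies of a common
hairpin; distances are 1 - (global alignment identity), and the NJ tree
reflects the divergence order.
"""

import numpy as np

from mirhunt.io_formats import SequenceRecord
from mirhunt.phylo import identity_distance, neighbor_joining

rng = np.random.default_rng(6)
base = "".join(rng.choice(list("ACGU"), size=120))


def diverge(seq, n_subs, rng):
    out = list(seq)
    for p in rng.choice(len(seq), size=n_subs, replace=False):
        out[p] = rng.choice([b for b in "ACGU" if b != out[p]])
    return "".join(out)


family = [SequenceRecord("pre-miR-demo-a", "", base)]
for label, subs in (("b", 4), ("c", 8), ("d", 20), ("e", 40)):
    family.append(SequenceRecord(f"pre-miR-demo-{label}", "",
                                 diverge(base, subs, rng)))

dm = identity_distance(family)
print("identity distances to member a:",
      ", ".join(f"{t}={d:.3f}" for t, d in zip(dm.taxa[1:], dm.d[0, 1:])))
tree = neighbor_joining(dm)
print("newick:", tree.newick())
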