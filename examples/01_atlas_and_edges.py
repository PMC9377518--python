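"""The 90-region atlas, its six functional networks, and canonical edge indexing.

Every analysis in this package works on the 4005 unordered region pairs of a
90-region parcellation, stored in one fixed row-major upper-triangle order.
"""

import numpy as np

import fcmvpa as f

atlas = f.build_default_atlas()
print(atlas)
print(f"{atlas.n_regions} regions -> {atlas.n_edges} edges")

counts = f.possible_edge_counts(atlas)
print("\nPossible region pairs per network pair (diagonal = within-network):")
print(counts)
intra = int(np.diag(counts).sum())
print(f"\n{intra} possible within-network pairs, {atlas.n_edges - intra} between-network.")

k = f.edge_index(atlas.index_of("PHG.L"), atlas.index_of("IFGoper.L"), 90)
print(f"\nThe PHG.L–IFGoper.L connection is edge {k}; pair_of({k}) -> {f.pair_of(k, 90)}.")
# These numbers are the denominators used when selected-edge counts are
# standardized into percentages per network pair.
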