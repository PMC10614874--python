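"""Mapping ensemble spiking to the disjoint marked representation.

Builds a tiny 3-neuron raster, encodes each bin's spiking pattern as a mark
(the C-bit binary word with neuron c on the c-th least-significant bit),
recovers individual spike trains from the marks, and prunes the mark space to
the reliably occurring patterns.
"""

import numpy as np

from hocoord import (
    SpikeRaster,
    decode_mark,
    encode_mark,
    order_r_marks,
    recover_neuron,
    reliable_marks,
    to_marked,
)

raster = SpikeRaster(np.array([
    [1, 0, 0, 1, 0, 1, 0, 0],
    [0, 0, 1, 1, 0, 1, 0, 0],
    [0, 0, 0, 0, 0, 1, 0, 1],
]))

print("pattern [1,1,0] encodes to mark", encode_mark([1, 1, 0]))
print("mark 5 with C=3 decodes to pattern", decode_mark(5, 3))
# -> mark 3 and pattern [1,0,1]: neuron c occupies the c-th binary digit

marked = to_marked(raster)
print("\nevent times:", marked.times.tolist())
print("their marks:", marked.marks.tolist())
# bin 3 holds the simultaneous pattern {1,2} -> mark 3; bin 5 holds the
# triple coincidence {1,2,3} -> mark 7

for c in (1, 2, 3):
    assert (recover_neuron(marked, c) == raster.data[c - 1]).all()
print("round trip: each neuron's train equals the sum of its marks")

print("\n3rd-order patterns for C=3:", order_r_marks(3, 3).tolist())
space = reliable_marks(marked, n_thr=0)
print("marks with at least one event:", space.reliable.tolist())
# the counts below drive pruning: marks above the threshold stay in the model
print("event counts per mark:", dict(enumerate(marked.counts(), start=1)))
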