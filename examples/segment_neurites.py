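"""Neurite/cell area ratio on a synthetic F-actin field.

Generates one neuron-like cell with a known soma and neurite, segments it,
splits soma from neurites and prints the neuritogenesis marker next to its
ground-truth value.
"""

import nquant as nq

spec = nq.CellSpec(soma_center=(80, 60), soma_radius=10,
                   neurites=[([(80, 70), (80, 150)], 3.0)])
scene = nq.generate_neuron_scene([spec], nq.ImagingParams((160, 220), seed=1))

labels = nq.segment_cells(scene.channels["actin"], min_cell_area=100)
morph = nq.split_soma_neurites(labels == 1, soma_opening_radius=7)
summary = nq.neurite_ratio_summary([morph])

truth_ratio = (scene.truth.neurite_masks[0].sum()
               / scene.truth.cell_masks[0].sum())
print(f"soma area:            {morph.soma_area} px")
print(f"neurite area:         {morph.neurite_area} px")
print(f"neurite/cell ratio:   {morph.ratio_neurite_cell:.3f}")
print(f"ground-truth ratio:   {truth_ratio:.3f}")
print(f"cells in summary:     {summary['n_cells']}")
# The ratio is the fraction of the cell footprint occupied by processes;
# higher values mean more neurite outgrowth relative to the cell body.
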