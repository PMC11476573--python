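# Per-side interacting-atom counts (3.5 A close-contact cutoff) reported for
# ten candidate HSA-ACE complexes from rigid-body macromolecular docking.
# columns: complex_id, n_atoms_hsa, n_atoms_ace
1	372	396
2	319	287
3	278	267
4	540	543
5	347	327
6	472	432
7	447	444
8	362	390
9	351	352
10	267	231
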