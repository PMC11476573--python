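# ifacekit

Characterization of protein–protein interfaces for docked and MD-simulated
complexes, built around the human serum albumin (HSA) – angiotensin
I-converting enzyme (ACE) system: which atoms touch, which residue pairs
form hydrogen bonds or salt bridges, how long those interactions survive a
simulation, which candidate binding pose engages the largest interface, and
what a point mutation at the interface is likely to do.

It is written for structural bioinformaticians triaging macromolecular
docking output: docking servers return many candidate poses of two large
proteins, binding free energies are unreliable at that scale (the entropic
term in particular), and a robust alternative is to score poses by the
*number of atoms in steric and polar contact* and then watch which specific
interactions persist under molecular dynamics.

## What it computes

Given a two-group structure (e.g. chains assigned `HSA=A`, `ACE=B`):

- **Close contacts** — all inter-group atom pairs within a cutoff
  (3.5 Å inclusive by default), per-side unique-atom counts, and the
  interface residue lists. The KD-tree search is verified against an
  all-pairs oracle.
- **Specific interactions** — hydrogen bonds (geometric criteria, with a
  hydrogen-free fallback for structures lacking hydrogens) and salt
  bridges (charged-group N–O pairs within 4.0 Å), with backbone
  participation annotated in the literature's superscript style:
  `Asp38-Lys622 (SB)`, `Cys34^O-Gln807 (HB)`.
- **Pose ranking** — engagement score per candidate complex; the default
  `min(n_atoms_A, n_atoms_B)` statistic is symmetric in the partners and
  penalizes lopsided interfaces.
- **Occupancy / lifetime** — per-frame interaction tracking over a
  trajectory keyed by (residue pair, kind); lifetime as a percentage of the
  run; a strict `> 50%` persistence filter; endpoint contact tables; Cα
  RMSD with Kabsch superposition.
- **Mutation triage** — rule-based classification of interface point
  mutations (charge reversal at a salt bridge, donor/acceptor-preserving
  swaps, bulk loss, new-salt-bridge candidates) on wild-type geometry.
- **Bookkeeping** — histidine protonation tags (HID/HIE/HIP), formal
  charges at pH 7, counterion counts, glycan-to-asparagine attachment, and
  functional-site proximity reports (e.g. albumin's Cys34, Tyr150, Tyr411,
  Lys525).
- **Synthetic data** — a seeded generator that *plants* contacts, hydrogen
  bonds, salt bridges and site distances at exact geometries, with a
  machine-readable truth ledger, plus trajectories realizing an exact
  per-interaction presence schedule. Every detector is tested against
  planted truth; no downloads are needed.

## Worked example

Rank the ten docked HSA–ACE candidate poses from their bundled per-side
interacting-atom counts, then check persistence on the bundled MD lifetime
table:

```python
from ifacekit.contact_analysis import rank_complexes
from ifacekit.refdata import load_docked_contact_counts, lifetimes_as_records
from ifacekit.trajectory_analysis import persistence_filter

report = rank_complexes(load_docked_contact_counts())
print(report.order[:3])          # [4, 7, 6]
print(report.entries[0])         # (4, 540, 543, 540.0)

for cid in (4, 7, 6):
    survivors = persistence_filter(lifetimes_as_records(cid), 50)
    print(cid, len(survivors))   # 4 13 / 7 9 / 6 4
```

Complex 4 ranks first (540 atoms on its smaller side, against 444 for
complex 7 and 432 for complex 6), and 13 of its 23 specific interactions
persist for more than half of the 100 ns simulation — the strongest and
most persistent of the three MD-tested poses. The same numbers fall out of
a fully synthetic rerun: `ifacekit.refdata.lifetime_plant(4)` builds a toy
complex planting all 23 interactions, and `track_interactions` on a
scheduled 100-frame trajectory returns each lifetime exactly.

The same operations are available from the shell:

```sh
iface rank                       # bundled counts, min-side score
iface contacts model.pdb --groups HSA=A --groups ACE=B --cutoff 3.5
iface lifetimes traj.pdb --groups HSA=A --groups ACE=B --threshold 50
iface synth --seed 7 --out toy.pdb --ledger truth.tsv
```

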