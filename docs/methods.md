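# Methods

## Scope and model

ifacekit analyzes *pairs* of protein groups — two chain sets of one
structure, e.g. albumin vs ACE — and characterizes their interface at three
levels: steric engagement (close contacts), polar engagement (hydrogen
bonds and salt bridges), and persistence of the polar engagement over a
trajectory. Everything is geometric; there is no energy model, no hydrogen
building, no minimization, and no side-chain rebuilding. Those preparation
steps belong to external tools, and the package is written to work on their
output (or on raw crystallographic/cryo-EM coordinates via the
hydrogen-free fallbacks described below).

Author residue numbering with insertion codes is the canonical label space
throughout, because that is how interface residues are identified in the
literature (Cys34, Lys622, Asn685). Alternate locations keep the
highest-occupancy conformer (ties break to the lexicographically first
altloc), since single-conformer geometry is what contact counting assumes.

## Close contacts

A close contact is an inter-group atom pair with Euclidean distance
≤ cutoff, *inclusive*; the default cutoff is 3.5 Å. Hydrogens are excluded
from contact counting by default because docked and crystallographic inputs
frequently lack them, which would otherwise make per-side atom counts
incomparable across inputs; the flag is recorded in every contact set. The
KD-tree accelerated search (scipy cKDTree) is required to be *exactly*
equivalent to the all-pairs double loop; both paths compute the reported
distance with the same floating-point expression, and the equivalence is
asserted over 100 seeded toy complexes.

Per-side counts `n_atoms_A` / `n_atoms_B` are unique atoms appearing in any
qualifying pair. The ranking statistic for candidate poses defaults to
`min(n_atoms_A, n_atoms_B)`: it is symmetric in the two proteins, rewards
balanced engagement, and is the statistic consistent with the published
ordering of the ten docked albumin–ACE poses (4 > 7 > 6, where a raw sum
would transpose 7 and 6). `sum`, `side_a` and `side_b` scores are
selectable. Ties break deterministically by complex id.

## Hydrogen bonds and salt bridges

Hydrogen-bond criteria (defaults): donor–acceptor heavy-atom distance
≤ 3.5 Å; in hydrogen-aware mode additionally H···acceptor ≤ 2.5 Å and
D–H···A angle ≥ 120°. These are the common geometric definitions; the mode
auto-detects whether the structure carries hydrogens, and requesting
hydrogen-aware criteria on a hydrogen-free structure is an error rather
than a silent downgrade. In the hydrogen-free fallback only the
donor–acceptor distance applies, restricted to *typed* N/O donor and
acceptor atoms given the residue type and histidine protonation tag
(HID donates Nδ and accepts Nε; HIE the reverse; HIP donates both).

Salt bridges: one bridge per (cationic group, anionic group) pair whose
minimum nitrogen–oxygen distance is ≤ 4.0 Å. Cationic groups are Lys NZ,
Arg NE/NH1/NH2, doubly protonated histidine, and the free N-terminal amine
of chains flagged as having free termini; anionic groups are Asp OD1/OD2,
Glu OE1/OE2 and the free C-terminal carboxylate. An atom pair satisfying
both definitions is reported once, as a salt bridge, matching the
one-row-per-pair convention of published interface tables.

Multiple atom-level geometries between one residue pair and kind collapse
to a single record keeping the shortest distance; backbone-participation
flags accumulate over all contributing geometries, so a pair engaging both
its backbone carbonyl and amide reports `O,HN`. Backbone flags derive
purely from atom names: carbonyl O/OXT → `O`; amide N (and its hydrogens)
→ `HN`. Output is sorted by (residue A, residue B, kind), making repeated
runs byte-identical.

A published row typed as a backbone-amide "salt bridge" on a residue with
no free amine (no cationic group) is deliberately *not* special-cased; the
geometric rules classify it as a hydrogen bond.

## Occupancy, persistence, RMSD

Interaction identity across frames is the (residue pair, kind) key: any
qualifying atom geometry in a frame counts that frame as present, because
published lifetime tables are residue-pair rows, not atom-pair rows.
Occupancy = frames present / total frames; lifetime = occupancy × 100.
Frames are weighted uniformly with no smoothing. The persistence filter
keeps records with lifetime strictly greater than the threshold
(default 50%), matching the "persists over half the simulation" reading;
with the bundled published lifetimes, strict vs non-strict comparison is
indistinguishable (no value equals 50%), so the wording decides.

Cα RMSD superposes each frame onto the reference with a Kabsch fit
(scipy `Rotation.align_vectors`) over the Cα atoms of *both* groups
jointly — the series is meant to track whole-complex stabilization — then
averages over the same selection. Unsuperposed RMSD is available and is
never smaller than the superposed value.

## Formal charges and counterions

Residue charges at pH 7: Asp/Glu −1, Lys/Arg +1, His 0 in HID/HIE and +1
in HIP; +1/−1 free-termini charges apply only to chains explicitly flagged,
because cryo-EM and truncated constructs may have capped or unresolved
termini. Hetero entities take configured charges (Zn²⁺ +2, Na⁺ +1, waters
and the common N-glycan sugars 0); an unrecognized hetero entity is a hard
error, never a silent zero. Counterions needed = |net charge| when the
named species has the opposite sign, else 0. Histidines default to HIE
(the common neutral tautomer for solvent-exposed residues), overridable per
residue.

## Mutation triage rules

Classification argues from wild-type geometry only. Rules apply in a
configurable order (defaults shown):

1. residue in a salt bridge, variant reverses side-chain charge sign →
   `weaken` / `charge_reversal_at_SB`;
2. residue in a hydrogen bond, variant retains an equivalent
   donor/acceptor (configurable table, seeded with Asp↔Asn, Glu↔Gln,
   Ser↔Thr) → `neutral` / `hb_preserving_swap`;
3. residue in steric contact, variant loses ≥ 3 side-chain heavy atoms or
   an electrostatically engaged charge → `weaken` / `bulk_and_charge_loss`;
4. residue within the proximal band (default 8 Å) with *no* specific
   interaction, variant's new charge opposite to a charged partner residue
   within that band → `strengthen_candidate` / `new_SB_possible` — note a
   residue in plain steric contact is eligible here, which is what lets a
   buried-but-unbonded lysine be flagged as a salt-bridge candidate after
   charge reversal;
5. distal → `none` / `no_interface_role`.

An interface residue whose substitution matches no rule classifies
`neutral` with no rationale code — the enum of rationale codes covers the
decisive rules, not the benign fallthrough. The 8 Å proximal band is a
deliberately generous "near the interface" default for qualitative
statements; it is configurable.

## Synthetic data: what it emulates and what it does not

The generator builds two-chain complexes from a reduced residue
representation: the four backbone atoms plus side-chain pseudo-atoms with
real PDB names, spaced ≥ 1.2 Å apart along the side-chain axis. Each
planted item (contact, HB, SB, site distance) occupies its own interface
slot 12 Å from its neighbors; the partner residue is positioned so the
designated atom pair realizes the target distance exactly, with every other
atom retracted far enough that *only* the planted pair can satisfy any
criterion (the no-accidental-interaction property is asserted by
brute-force scans in the tests, not assumed). Hydrogens are added only when
a plant specifies a D–H···A angle. Filler residues sit across a 30 Å
inter-chain gap. Functional-site plants use widely separated slots (60 Å)
so the planted distance is exactly the minimum to the partner group.
Glyco-mediated contacts attach a reduced NAG stub to its asparagine at
bonding distance, exercising the glycan-inherits-anchor annotation.

Trajectories realize a per-interaction schedule exactly:
`round(fraction × n_frames)` present frames, chosen by a seeded
permutation. Present frames restore the planted geometry with jitter capped
at 0.02 Å (inside every criterion's margin); absent frames displace the
partner residue 8 Å away, exceeding every criterion by more than 1.5 Å;
all other atoms get the full requested jitter (default 0.05 Å). The seed
fully determines output; different seeds differ.

What this does *not* emulate: real rotamer geometry, cooperative or
correlated interaction dynamics, water-mediated bridges, conformational
drift, or crystallographic disorder. Passing the recovery tests therefore
demonstrates the *detectors and bookkeeping* are correct, not that the
geometric criteria are optimal for any particular real system.

The bundled reference tables (per-side interacting-atom counts of ten
docked albumin–ACE poses; interaction lifetimes of the three MD-simulated
leaders) are published characterization results used as *inputs* to the
ranking and persistence stages and as schedule templates; the synthetic
stand-ins built from them echo the published residue labels, with a residue
appearing in two table rows duplicated under a bumped author number so each
planted pair keeps its own interface slot.

## Numerical choices and problem sizes

Distances compare with `<=` everywhere ("no more than"). Both contact
search paths share one floating-point distance expression so their outputs
compare exactly. Ranking and interaction ordering use explicit
deterministic tie-breaks (complex id; residue sort keys). The acceptance
suite runs entirely on synthetic scale — toy complexes of tens of residues,
100-frame schedules, 100 seeded oracle comparisons — which keeps the full
suite in seconds while exercising every code path at the fidelity the
planted-truth ledgers guarantee.

## Known limitations

- Two checks depend on deposited PDB entries (the prepared albumin + ACE
  system's 44-sodium neutralization; the albumin–FcRn interaction-count
  calibration). The entries are too large to bundle and the second
  additionally requires hydrogen building and minimization, which are out
  of scope; the corresponding tests run the real computation when the
  files are supplied locally and report the missing input otherwise.
- π–cation, π–π, hydrophobic-cluster and water-mediated interactions are
  not detected.
- The hydrogen-free hydrogen-bond fallback cannot check angles and will
  over-count relative to hydrogen-aware criteria on dense polar interfaces.
- Mutation triage is qualitative by design: no ΔΔG, no rotamer sampling,
  no stability estimate.
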