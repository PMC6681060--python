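# Methods

## Model

LID (Local Interaction Density) treats the interactions observed across an
ensemble of reference protein–ligand complexes as an empirical density over
space, factored into 21 channels (7 interaction types × 3 position tags),
and scores a docking pose by how much of that density its own interactions
recover.  The core assumptions are:

* **Shared frame.**  All references and all poses are expressed in the
  frame of one representative structure.  The method is sensitive to
  superposition quality by construction; it trades the alignment-free
  flexibility of graph-matching approaches for per-pose scoring cost that
  is linear in the number of pose IPAs.
* **Positive, unweighted evidence.**  Every matched interaction adds to
  the score; absence of an interaction never subtracts, and no interaction
  type is weighted above another.  Normalizing each channel by the pose's
  own IPA count in that channel stops IPA-rich types (typically
  hydrophobic contacts) from dominating.
* **Counting, not smoothing.**  Densities are integer IPA counts.  The
  only spatial tolerance is the fixed Manhattan neighborhood; there is no
  Gaussian kernel, so the score is exactly reproducible and cheap.

## Geometry and numerics

* **Voxelization.**  Grid origin = per-axis minimum IPA coordinate minus
  half an edge, so the extreme IPAs sit at voxel centers.  A point belongs
  to voxel `floor((p − origin)/edge)` (half-open intervals; boundary points
  go to the higher index).  Default edge 0.1 Å.
* **Neighborhood.**  "Within a Manhattan distance of 0.5 Å" is applied to
  voxel index triples: L1 distance ≤ `neighborhood/edge` = 5 voxels.  A
  dense 0.1 Å grid over a ~30 Å site would need ~10⁸ voxels per channel,
  so only occupied voxels are stored (hash of index triples).  Two
  read-out strategies are implemented and tested to agree exactly: lazy
  enumeration of the 231-voxel L1 ball, and a precomputed dilated table.
* **Out-of-grid queries** return density 0 rather than raising: docking
  poses may legitimately protrude from the crystallized envelope.
* **Empty channels / empty poses.**  A pose channel with no map density
  contributes 0.  An empty pose (no detected interactions) scores 0 with a
  warning rather than an error, so screening runs never abort.
* **Ranking ties** are broken by descending docking score when available
  (poses arrive pre-scored by the docking program), else by input order.
* **Superposition** is least-squares rigid (Kabsch via SVD) on site Cα
  atoms matched by (chain, residue number, residue name); the
  representative minimizes the mean pairwise site-Cα RMSD, ties broken by
  lexicographic id.  Pairs with < 3 common site Cα get RMSD +∞ with a
  warning.

## Interaction rules (defaults, all overridable)

Only the π-stacking centroid cutoff (5.0 Å) is a method-defining constant;
the remaining thresholds are standard crystallographic contact criteria:

| rule | default |
|---|---|
| H-bond donor–acceptor heavy-atom distance | ≤ 3.5 Å |
| H-bond D–H…A angle (when the donor has an explicit H) | ≥ 120° |
| ionic: opposite-sign charged-group center distance | ≤ 4.5 Å |
| metal chelation: metal to ligand N/O/S | ≤ 2.8 Å |
| hydrophobic apolar C/S pair distance | ≤ 4.5 Å |
| π-stacking centroid distance | ≤ 5.0 Å |
| π-stacking interplane angle | ≤ 30° (face) or 60–90° (edge) |

Perception: ligand donors come from explicit hydrogens when the molecule
has any, else from SYBYL-type/element lookup; ligand formal charges from
the Mol2 charge column (or PDB charge columns); protein donors, acceptors,
charged groups, aromatic rings and apolar atoms from per-residue atom-name
templates (`lid.chemdata`), the usual approach for hydrogen-free protein
models.  Aromatic carbons are excluded from the hydrophobic pair rule —
stacked rings are already captured by the π-stacking type, and counting
each of their ~20 carbon pairs as separate hydrophobic records would
swamp the maps with redundant IPAs.  Hydrophobic contacts are emitted one
record per atom pair by default, with an optional per-ligand-atom
clustering switch.  Cation–π interactions and halogen bonds are out of
scope; waters are removed upstream, so water-mediated bridges never arise.

Alternate locations in PDB input keep the highest-occupancy copy.
Unselected HET groups are treated as cofactors and dropped (configurable
exclusion list); single-atom metal HET records become site metals, and
crystallization additives are selected like any ligand — additive-only
("apo") references need no special code path.

## Synthetic data: what it emulates and what it does not

The generator builds a toy site from real residue templates (Gly, Asp,
Lys, Phe, Leu, plus Zn) placed on a 10 Å circle, one "station" per planted
interaction type, and a ligand pseudomolecule with one functional group
per station.  Stations are spaced so that exactly one rule window is
satisfied per group: at zero jitter, detection recovers the planted truth
atom for atom (the closure tested in `tests/test_synthetic.py`).

Two noise knobs emulate crystallographic variability:

* `ligand_jitter` (default 0.25 Å σ): per-reference rigid displacement of
  each ligand group — binding-mode variability around a conserved motif.
  Jittered instances that leave a rule window are legitimately missed by
  the detector; that is the emulated disorder, not a bug.
* `site_jitter` (default 0): per-reference rigid displacement of a whole
  station (residue + ligand group) — side-chain flexibility.  The
  flexible-site scenarios use 0.8 Å (titration) and 1.5 Å (additive
  contrast), roughly the all-atom site RMSD regime where additive-guided
  rescoring is expected to break down.

What passing these benchmarks shows: the geometry, bookkeeping and scoring
machinery are exact (oracle agreement), and the score behaves as designed
(near-native poses dominate displaced ones once ≥ 3 references are fused;
information accumulates with reference count; additive-only maps suffice
on a rigid site and fail on a flexible one).  What it does not show:
performance on real PDB ensembles — real sites have correlated backbone
motion, tautomers, waters, and interaction perception noise that the toy
site deliberately omits.

## Study sizes

The packaged studies are sized for seconds-scale runs: 5 references ×
~21 IPAs each for the rigid discrimination study (10 replicate complexes,
10 poses each), a 10-reference pool with ≤ 30 subsets per n for the
titration, 6 additive references for the apo contrast, and 500–1000 random
IPAs for the oracle-agreement checks.  The titration study orders displaced
poses before near ones within each pose list, so an all-zero score tie
resolves to a wrong pose — emulating the hard case where the docking
score ranked a decoy pose first and rescoring must overturn it.

## Known limitations

* Interaction rules are a documented, self-consistent rule set, not a
  bit-for-bit reproduction of any particular fingerprinting program.
* Residue templates cover the 20 standard amino acids; modified residues
  contribute only backbone donors/acceptors.
* The grid is not padded beyond the IPA bounding box; the neighborhood sum
  itself provides the edge tolerance, and queries outside score 0.
* Graph-automorphism RMSD enumeration is capped (10⁴ mappings) and warns
  when truncated; highly symmetric ligands may report an upper bound.
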