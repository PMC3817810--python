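# Methods

This note records the model, the defaults, the numerical choices, and the
limits of what the shipped tests demonstrate.

## Mechanical model

**Bodies.** The strong-bond graph contains all inferred covalent bonds plus
every *strong* hydrogen bond. Each multivalent atom (two or more strong
neighbors) is the central atom of exactly one rigid body consisting of
itself and its strong neighbors; monovalent atoms belong to their
neighbor's body; connected groups with no multivalent atom (isolated atoms,
diatomics) become a single body with no central atom. A strong bond whose
two atoms are both central is a **hinge** (the two bodies overlap in the
bonded pair); the hinge is locked when the bond is non-rotatable (peptide
bonds, carbonyl and side-chain sp2 double bonds, aromatic and proline
rings).

**Strong H-bonds.** A strong H-bond contributes its H–A contact to the
strong-bond graph. The hydrogen then has two strong neighbors (D and A),
becomes central, and the D–H and H–A bonds become hinges — the construction
that fixes bond length *and* the angles at the incident atoms, exactly as a
covalent bond does. The H–A hinge is left rotatable; a switch to lock it is
a one-line change in `build_model` but is not exposed, as the rotatable
variant is the conservative choice.

**Bars.** Weak H-bonds (when modeled rather than dropped) are single bars
H↔A; legacy hydrophobic tethers are 2 bars; LJ-scored hydrophobics are
single bars. A bar endpoint attached to a central atom is placed on the
vertex of the body centered at that atom; non-central endpoints belong to
exactly one body. This rule resolves the bar–hinge ambiguities introduced
by multi-base acceptors; bar–bar concurrencies (furcated bonds) need no
special handling because the multigraph is well defined. Bars whose two
endpoints resolve to the same body constrain nothing and are dropped
(counted on the model). Parallel edges are capped at 6 per body pair; the
excess is recorded as trivially redundant, which is what the pebble game
would conclude anyway.

**Genericity.** The combinatorial count certifies rigidity only for generic
geometric realizations. Concurrent bar endpoints and bars ending on hinges
are combinatorially non-generic; the endpoint-resolution heuristic above
lets the pebble game run on them, but no attempt is made to detect
non-generic coordinate geometry. Results on such configurations are
heuristic, as is standard for this class of method.

## Pebble game

The (6,6)-pebble game assigns 6 pebbles per vertex; an edge is accepted
(independent) iff 7 pebbles can be gathered onto its endpoints, which costs
one pebble and orients the edge; pebble searches are depth-first with
neighbors visited in vertex-id order, and edges are processed in input
order, so results are deterministic. The independent-edge *set* can depend
on edge order; the counts, free-pebble total, and rigid components cannot
(matroid property, exercised by tests).

Rigid components are computed as equivalence classes of pairwise mutual
rigidity ("cannot gather 7 pebbles on the pair"), one union-find pass per
connected component. Two overlapping rigid sets always merge into a rigid
set under the 6n−6 count, so the classes are well defined; bodies in no
larger class are emitted as singleton components. Internal DOFs are
`total_free_pebbles − 6·(number of connected components)`, i.e. trivial
rigid motions are discounted per connected component.

`sparsity_oracle` re-derives everything by exhaustive subset enumeration
(|V| ≤ 12) and serves as an independent ground truth in the tests: 200
seeded random multigraphs (|V| ≤ 8, ≤ 30 edges) must agree exactly.

## Interactions

**Covalent bonds** are inferred from distances (Cordero covalent radii
+0.45 Å; S–S ≤ 2.3 Å flagged disulfide). Side-chain planarity is assigned
from residue templates (ARG guanidinium, carboxylates, amides, aromatic
rings, proline ring).

**Hydrogen bonds** use HBPLUS-like geometric defaults, all overridable:
d(D···A) ≤ 3.9 Å, d(H···A) ≤ 2.5 Å, θ(D-H-A) ≥ 90°, donors/acceptors in
{N, O, S}. Energies come from the Mayo-style closed form with V₀ = 8
kcal/mol, d₀ = 2.8 Å and a hybridization-dependent angular factor:
sp3/sp3 cos²θ·cos²(φ−109.5°); sp3 donor/sp2 acceptor cos²θ·cos²φ; sp2
donor/sp3 acceptor cos⁴θ; sp2/sp2 cos²θ·cos²(max(φ,γ)). γ is measured as
180° minus the deviation of the hydrogen from the acceptor's sp2 plane, so
that in-plane geometry maximizes the factor. Candidates with repulsive
(positive) energy are discarded; hybridization comes from residue/atom-name
templates with element fallbacks. Only backbone amide hydrogens are ever
placed by the package (in-plane bisector, N–H 1.0 Å); side-chain polar
hydrogens must be present in the input or their H-bonds are invisible —
a deliberate limitation, since backbone H-bonds carry secondary structure.

**Hydrophobics.** The legacy heuristic reproduces the C/S
van-der-Waals-surface rule (Bondi radii, 0.25 Å surface cutoff, same
residue and ≤ 3 covalent bonds excluded) and carries no energy (NaN
sentinel; the energy filter refuses it). The Lennard-Jones method scores
every heavy-atom pair within r_max (default 6.0 Å — our choice; beyond it
|V| < 0.01 kcal/mol for these parameters) excluding same-residue, 1-2 and
1-3 pairs; 1-4 pairs are kept. Per-element parameters are Amber-99-style
(ε in kcal/mol, Rmin/2 in Å): C (0.1094, 1.908), N (0.17, 1.824),
O (0.21, 1.6612), S (0.25, 2.0), with Lorentz–Berthelot mixing. Full
per-atom-type Amber typing would change individual energies by a few
hundredths of kcal/mol and is out of proportion for a pairwise contact
screen.

## Residue-level conversion

For each atom cluster, a residue joins when its CA is in the cluster and
neither its C–CA nor CA–N bond still *rotates*. An unlocked hinge rotates
only while its two bodies are in different rigid clusters; once welded into
one cluster, the rotation is inhibited by the constraint network and the
bond no longer disqualifies the residue. (The naive reading — any unlocked
hinge disqualifies — would make every residue a singleton in every protein,
since backbone N–CA and CA–C are always rotatable bonds.) A residue claimed
by several clusters goes to the largest (ties: the first built); residues
claimed by none, or missing a CA, become singletons, so the output is
always a partition.

## Scoring

B-cubed per-item precision/recall with arithmetic means and harmonic-mean
F1; comparisons against printed reference values round half-away-from-zero
to 2 decimals, full precision is kept internally. Universe mismatches are
padded with singletons on the deficient side (with a warning). Cutoff
sweeps maximize F1 with ties resolved toward the most negative H-bond
cutoff, then the most negative hydrophobic cutoff. Paired method
comparisons use the two-sided paired t-test; when the score differences
have zero variance the statistic is undefined and the result is flagged
degenerate (p = 1.0 exactly when the mean difference is also 0).

## Fixtures and what the tests show

The fixture builders are seedless and bit-stable: staggered ethane
(C–C 1.54 Å, C–H 1.09 Å, tetrahedral angles) and an ideal polyalanine
α-helix (φ = −57°, ψ = −47°, ω = 180°, Engh–Huber-style bond lengths and
angles, amide H in the peptide plane, CB with L-chirality; the N-terminal
residue has no amide H). The helix reproduces textbook geometry — 1.56 Å
rise per residue, O(i)···N(i+4) = 3.09 Å — and yields exactly 14 backbone
H-bonds at −4.9 kcal/mol, inside the −7..−2 kcal/mol band expected for
α-helical H-bonds.

These fixtures exercise every code path but are *ideal* geometry: no
side chains beyond CB, no solvent, no crystallographic noise, no missing
atoms, no furcated H-bonds (a synthetic clash fixture covers those labels).
Passing tests therefore demonstrate correctness of the mechanics, the
energies, and the scoring algebra — not predictive accuracy on real
proteins, which additionally depends on curation quality and on the energy
cutoffs chosen. Real-protein benchmarking (external PDBs plus
RigidFinder-style gold standards) runs through
`scripts/reproduce_benchmark.py`, which reports scores without asserting
them.

## Problem sizes

The shipped tests and the acceptance script run on desk-scale inputs: the
10-residue worked example, the 18-residue helix (107 atoms, 81 bodies) and
random multigraphs with at most 8 vertices and 30 edges; the whole suite
completes in a few seconds. The pebble game itself is quadratic and handles
protein-sized graphs; the rigid-component pass tests each vertex against
each existing class and is the dominant cost on large inputs.
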