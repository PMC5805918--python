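# Methods

## Model

Clusters are collections of rigid molecules: TIP4P water and one C₃ᵥ
pyramidal anion (sulfite SO₃²⁻ or chlorate ClO₃⁻). The interaction
energy is the sum over all inter-molecular site pairs of a Coulomb term
k_C·q_iq_j/r and a 12-6 Lennard-Jones term 4ε_ij[(σ_ij/r)¹²−(σ_ij/r)⁶];
there are no cutoffs, periodic images, polarization or many-body terms —
the systems are finite gas-phase clusters of at most ~50 molecules.
k_C = 332.0637 kcal·Å·mol⁻¹·e⁻² and k_B = 0.0019872 kcal·mol⁻¹·K⁻¹ are
defined once in `constants.py`.

**Water.** Four sites: an LJ-only oxygen, two +0.52 e hydrogens, and a
massless −1.04 e lone-pair (M) site 0.15 Å from the O on the H–O–H
bisector; O–H = 0.9572 Å, H–O–H = 104.52°. Two oxygen LJ parameter sets
are built in: `canonical` (ε = 0.1550 kcal/mol, σ = 3.15365 Å — the
standard TIP4P values; the default) and `as_printed`
(ε = 0.648 kcal/mol, σ = 3.2 Å). The published parameter table lists
0.648 under a kcal/mol header, but 0.648 kJ/mol equals the canonical
0.155 kcal/mol, so the table value is read as a kJ number under a
mislabelled header; the strict reading remains available for sensitivity
work.

**Ions.** Rigid C₃ᵥ pyramids with the apex atom on +z and the centre of
mass at the origin. Apex height follows from bond length L and O–X–O
angle θ via h² = L²(cosθ + ½)/1.5 (θ = 120° is the planar limit); a
user-supplied height inconsistent with (L, θ) warns rather than errors.
LJ parameters and partial charges are the published values:
S (0.25, 3.6 Å, +0.281 e), O_sulfite (0.25, 3.2 Å, −0.760 e),
Cl (0.040, 4.86 Å, +0.452 e), O_chlorate (0.076, 3.10 Å, −0.484 e).
The sulfite charges are rounded to 3 d.p. and sum to −1.999 e, so the
species carries an explicit charge tolerance instead of pretending the
sum is exactly −2.

**Sulfite geometry.** The published model description states
S–O = 1.9 Å with θ = 106° and h = 0.76 Å. This triple is over-determined
(L = 1.9, θ = 106° derives h = 0.735 Å; h = 0.76 corresponds to
L ≈ 1.96 Å), and 1.9 Å is far outside the physical S–O distance of
~1.53 Å. The default species honours the stated L and θ and derives h.
However, with L = 1.9 Å **no** low-lying SO₃²⁻(H₂O)₈ minimum contains a
directed trimeric water ring under any parameter-set/combining-rule
combination we tried, which contradicts the reported global-minimum
topology (trimeric rings as the only closed loops; an almost-degenerate
second minimum differing by ring-direction reversal). With the physical
L = 1.53 Å the global minimum carries exactly that topology, with
near-degenerate partners 0.04–0.13 kcal/mol up and a ~0.9 kcal/mol
single-saddle barrier to the nearest ring-rearranged partner. The
landscape experiments (`experiments.py`) therefore use
`sulfite(bond_length=1.53)`; this choice was made on structural-topology
grounds and is the package's interpretation of a suspected transcription
artifact in the source geometry.

**Combining rules.** Unlike-site LJ parameters default to geometric
means for both σ and ε (the OPLS/TIP4P convention); Lorentz–Berthelot is
switchable. A sensitivity check on the sulfite octahydrate gave an
almost identical landscape (GM −200.07 vs −200.12 kcal/mol, same ring
topology, nearest-partner barriers 0.9–1.6 kcal/mol), so the choice is
not critical at the accuracy of interest.

## Coordinates, gradients, quenches

Configurations are 6M-vectors: per molecule a COM translation and a
rotation vector (angle-axis, wrapped to |p| ≤ π). Analytic gradients use
the closed-form derivative of the rotation matrix with respect to the
rotation-vector components; correctness is enforced by finite-difference
tests at relative error 1e-6. Local quenches run an L-BFGS (memory 8,
Armijo backtracking, per-step displacement cap) compiled with numba,
with a scipy L-BFGS-B polish if the jitted loop stalls; the convergence
contract is gradient max-norm ≤ 1e-5 kcal·mol⁻¹·Å⁻¹ by default
(1e-3–1e-4 is adequate inside basin-hopping; databases are re-quenched
tightly by `refine_database` before landscape work, because loosely
quenched walks occasionally record near-flat saddle regions — e.g. the
water-trimer flip plateau — as minima).

Quenched structures with any inter-molecular site pair closer than
0.9 Å are rejected as charge-collapse artifacts (the closest physical
contact, H···M, stays above ~1.4 Å).

## Basin-hopping

Blocks of 100 moves of one class, cycling translate → rotate →
cycle-invert; a quench after every move; Metropolis acceptance on
quenched energies at kT = 1.0 kcal/mol (an acceptance temperature — the
130 K analysis temperature is a separate concept). Translation moves
displace every COM by an independent vector uniform in a 1.0 Å ball;
rotation moves compose every orientation with a random rotation of angle
≤ π; cycle-inversion picks a directed water H-bond cycle at random and
re-aims each member's donated OH at its predecessor's oxygen (COMs
fixed), falling back to a rotation move when no cycle exists (the
fallback is counted in the run statistics). Initial configurations place
waters uniformly in a sphere of radius ~2·M^(1/3) Å around the ion with
overlap re-draws. A drift guard recentres accepted configurations and
rejects quenches that leave a molecule beyond 3× the reference cluster
radius.

The minima database deduplicates on energy (1e-4 kcal/mol) plus a
structural check (sorted inter-molecular COM-distance multisets within
1e-3 Å) so that accidental energy degeneracies — ring-direction isomers,
enantiomers — stay distinct records. Runs are bitwise reproducible given
their seed.

## Hydrogen-bond analysis

An O–H donates to an acceptor oxygen (water or ion; ions never donate)
when H···O ≤ 2.5 Å and the O–H···O angle at the hydrogen is ≥ 120°; if
several acceptors qualify the shortest H···O wins, so each H donates at
most once. The criterion is a package convention (the original model
description states none) and every reported statistic records the
criterion used;
tightening the cutoffs can only remove edges. Ring counts use the
minimal cycle basis of the undirected graph, so a cubic octamer counts
as its 4-rings rather than the composite longer cycles; acceptor
capacity is uncapped. The conservation identity
(donated edges) + (dangling OH) = 2·n_waters is asserted on every
analyzed configuration in the tests.

## Boltzmann-weighted observables

w_i = exp(−β ΔU_i)/Z with ΔU_i the energy above the putative global
minimum, evaluated via log-sum-exp so windows spanning 10⁴ kcal/mol
remain finite. T defaults to 130 K. Three windows are explicit: all
unique minima (energy-per-water curves), the 1000 lowest (ion
coordination, displacement ratio), and ΔU ≤ 5 kcal/mol (dangling-OH
suppression). The radius of gyration is mass-weighted over all massive
sites, ion included by default (`include_ion=False` gives the
waters-only alternative).

## Landscape machinery

Bands between minima interpolate translations linearly and orientations
by shortest-arc quaternion slerp, after endpoint alignment: global
Kabsch rotation + Hungarian permutation of identical molecules (iterated
from several candidate rotations — ion-frame-derived plus deterministic
random starts — scored by all-site RMSD) and per-molecule reduction by
body-frame proper symmetries (water C₂, ion C₃). Without this alignment,
band searches between database minima are dominated by irrelevant global
motions and permutation crossings.

DNEB uses 11 interior images by default, the energy-weighted upwind
tangent, spring constant max(1, |ΔE|) kcal·mol⁻¹·Å⁻², the doubly nudged
perpendicular spring portion, and FIRE relaxation converged on the RMS
perpendicular true gradient (1e-3). Interior band maxima seed hybrid
eigenvector-following: the lowest Hessian eigenpair is estimated from
gradient-only finite-difference curvature products (Lanczos via
`eigsh`, dense finite-difference Hessian as fallback and for index
checks), a Newton step walks uphill along the mode (capped at 0.25),
and FIRE minimizes in the orthogonal subspace. Accepted saddles satisfy
gradient max-norm ≤ 1e-5 with exactly one eigenvalue below −1e-4
(eigenvalues within ±1e-4 are treated as the six rigid-body zero
modes). Falling off ±0.2 along the mode and quenching identifies the two
connected minima.

Minima pairs are joined by a missing-connection strategy: Dijkstra on an
auxiliary graph whose unconnected edges are weighted by squared
structural distance (aligned all-site RMSD), attacking the narrowest gap
each round; repeated attempts at one pair escalate (more images, a small
deterministic transverse kick) because a single deterministic band
often relaxes to a high saddle. `refine_barrier` then drives the min-max
barrier down by searching for candidate paths whose existing saddles all
lie below the current barrier and closing their gaps. Min-max pathways
and barriers come from a union-find sweep over saddles in energy order;
disconnectivity trees evaluate superbasins at uniformly spaced levels
(ΔE = 0.35 kcal/mol default, presentational only) and are checked
against a brute-force all-pairs min-max closure on toy databases.

## Problem sizes and scaling

The survey-scale protocol behind the headline numbers
(`scripts/acceptance.py`) uses, per N=8 system, 2 × 10,000 basin-hopping
steps (merged, tightly re-quenched), partner selection among the minima
within 0.5 kcal/mol of the GM by oxygen-framework RMSD, ~12 DNEB
connection attempts plus ~25–35 refinement attempts, and a 400-step
reduced search for ClO₃⁻(H₂O)₅₀; it completes in roughly 15 minutes on
one core. The test suite runs the same protocols at further reduced
scale (6,000-step N=8 searches; 1,500-step N=10/N=20 hydration runs;
600-step N=20 energy-per-water run) chosen to keep the whole suite
interactive; reduced searches find the same global minima for these
sizes but sample fewer high-lying minima.

## Known limitations and deviations

- The published 3.5 kcal/mol GM↔Min2 barrier for ClO₃⁻(H₂O)₈ cannot
  coexist with the published 6.5 kcal/mol first transition state on the
  same pathway (a min-max barrier never exceeds any of its saddles).
  We reproduce the 6.5 first saddle; our desk-scale min-max barrier
  refines to ~8 kcal/mol and is expected to be search-budget dependent
  (the published landscape holds ~930,000 saddles).
- The sulfite GM↔partner barrier computes to ~0.9 kcal/mol against the
  published ~0.8, under the package's geometry interpretation above.
- Boltzmann-weighted ⟨U⟩/N lies below the −10 kcal/mol bulk TIP4P limit
  at every size we run (ion–water attraction dominates), approaching the
  limit from below as N grows — the curve direction, not a convergence
  claim.
- Basin-hopping at these scales is a sampling heuristic: global-minimum
  claims are putative, and weighted statistics over "all unique minima"
  depend on the search budget.
- The synthetic fixtures (dimer, trimer ring, cube, shells) are idealized
  geometries for H-bond-graph tests, not quenched minima; tests passing
  on them validate the graph conventions, not the thermodynamics of real
  clusters.
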