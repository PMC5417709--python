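# Methods

This note records the models, conventions, and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the design decisions taken where the underlying definitions admit more
than one reading.

## Structures and atom typing

PDB parsing is delegated to Biopython; the package's own containers hold
flat coordinate arrays so geometry stays vectorised. Alternate locations
collapse to the highest-occupancy conformer (ties resolve to altloc 'A'),
insertion codes are preserved as distinct residues, and residue numbering
is kept exactly as deposited. Waters (HOH) are stored apart from protein
atoms and only their oxygens are used.

Covalent bonds are inferred by distance: two atoms are bonded when their
separation is below the sum of their covalent radii plus 0.4 Å. PDB files
carry explicit connectivity only for heteroatoms, so distance inference is
the standard route. A *carbonaceous group* is a carbon with no covalent
neighbour among N, O, S — the head of a CHn unit. Hydrogens are never
counted as separate groups, so the count is robust to whether the input
carries hydrogens at all.

## Dehydrons

Backbone H-bonds pair an amide nitrogen with a carbonyl oxygen under
N···O ≤ 3.5 Å and N–H···O ≥ 120° when the amide hydrogen is present; for
hydrogen-free structures the heavy-atom fallback C=O···N ≥ 90° applies.
These cutoffs are common practice for geometric H-bond assignment and are
exposed as configuration. Sequence separation must be ≥ 2 within a chain
(the i,i+1 amide–carbonyl contact is covalent geometry, not a bond), each
donor keeps only its nearest qualifying acceptor, and proline cannot
donate (no amide hydrogen).

The wrapping number ρ of a bond counts carbonaceous groups inside the
union of two spheres centred on the donor and acceptor Cα atoms. The
default radius is 6.5 Å, the desolvation-domain convention of the wrapping
literature; it is configurable, and `calibrate_radius` sweeps a radius
grid against a reference bond so the convention can be pinned to a known
structure (for G93A SOD1, entry 2WZ6, the Cys111→Gly108 bond with ρ = 10
against a structure mean of 24). Groups belonging to the donor and
acceptor residues themselves count; a group inside both spheres counts
once.

Flagging uses the distribution of ρ over all backbone H-bonds of the
structure: a bond is a dehydron when ρ ≤ ⟨ρ⟩ − 1·SD. "Root mean squared
deviation" is read as the population standard deviation (n denominator);
the sample form is available via `sd_mode`. Boundary cases follow from the
rule being inclusive: if every bond has equal ρ the SD is zero and all
bonds sit exactly at the threshold, hence all are flagged; a single bond
is likewise flagged. Both are degenerate inputs, documented rather than
special-cased away.

## Local frustration

The classification procedure is potential-agnostic: any symmetric 20×20
residue-pair energy table can drive it. The shipped default is a
hydropathy-derived table, e_ij = −0.2·(h_i + h_j)/2 with Kyte–Doolittle
hydropathies, which reproduces the dominant trend of knowledge-based
contact potentials (hydrophobic pairs favourable). It is a deliberately
simple stand-in: published server results computed with a water-mediated
associative-memory Hamiltonian will not match contact-by-contact, and no
parity with any specific server is promised. What is reproducible — and
tested — is the decoy/Z-score machinery itself.

Contacts are residue pairs with minimum heavy-atom distance ≤ 5 Å
(sequence separation ≥ 2 intra-chain; inter-chain pairs always eligible).
Decoys mutate both residue identities jointly; exhaustive mode enumerates
all 400 ordered identity pairs. (Enumerating 210 unordered pairs is *not*
equivalent for the mean and SD — diagonal pairs would be re-weighted — so
ordered-400 is the canonical choice.) Sampled mode draws uniform pairs
under a seed and converges to the exhaustive statistics at the 1/√n
Monte-Carlo rate. Z = (⟨E_decoy⟩ − E_native)/SD; boundaries are applied
exactly as printed: Z ≥ 0.78 minimally frustrated, Z < −1 highly
frustrated, the closed band between (including Z = −1) neutral. A
zero-spread decoy distribution with a differing native energy raises an
error in the low-level API and is forced to neutral with a logged warning
in the end-to-end report, keeping the three-way partition total.

A contact is water-mediated when some water oxygen lies within 3.5 Å
(a typical water H-bond length; configurable) of a heavy atom of each
residue. Per-residue histograms attribute a contact to a residue when the
midpoint of its two closest heavy atoms falls within 5 Å of the residue's
Cα; residues with no contacts in their sphere are omitted, so every
reported fraction triple sums to 1.

## Trajectory analytics

Superposition fits every frame to the mean structure of a fit selection by
optimal rotation/translation (SVD Kabsch), iterating fit → new mean until
the mean converges; fitting on one chain leaves the partner chain free.
RMSF, PCA, and superposition all operate on Cα atoms by default — the
per-residue convention of fluctuation analysis. Windowed RMSF deviates
from the window's own mean structure, not the full-trajectory mean, so a
post-transition window reports only the fluctuation within that period.

Change points in residue-pair distance series are found with a two-window
mean-shift scan: at each frame the means of the leading and trailing
`min_dwell` windows are compared, excursions above `min_shift` are
localised at their strongest frame, and a dwell period must pass before
the next detection. The method is deterministic, recovers planted steps
within one dwell of the true frame, and reports the before/after means.
It is the simplest detector adequate for step-like transitions; gradual
drifts spread over more than a dwell will be missed or localised loosely.

PCA eigendecomposes the 3N×3N coordinate covariance of the fitted Cα
coordinates; eigenvalues are in Å², rank deficiency simply yields trailing
zero eigenvalues, and no mass weighting is applied (all Cα masses are
equal anyway). The inter-loop coupling of a mode is the cosine similarity
of the mode's mean displacement vectors over two disjoint selections;
|coupling| near 1 identifies the correlated breathing of the two
electrostatic loops within that mode.

## Solvation bookkeeping

ΔG = ΔH + n_waters × TΔS with TΔS = 7.5 kcal/mol per bound water at 298 K
(an average entropic cost per immobilised water from cluster
thermochemistry). The entropic term enters with positive sign: binding a
water costs entropy against a favourable negative enthalpy. The convention
and the per-water value are configurable. kT conversion uses
k_B = 0.0019872 kcal mol⁻¹ K⁻¹, and the crowding-significance check is a
strict "greater than" against a 3 kT default threshold (the crowding
literature quotes ≈ 3–4 kT as the gain needed before a conformer
population matters). The module never computes ΔH itself; quantum-chemical
enthalpies are inputs.

## Synthetic generators

Backbones are built from internal coordinates (standard bond lengths and
angles, NeRF placement) at repeating (φ, ψ); the ideal helix uses
(−57°, −47°), which satisfies the H-bond criteria for every i→i−4 pair by
construction, and emits that list as ground truth. The planted-defect
helix is poly-alanine (each CB a wrapping group) with a five-residue
glycine window around one bond, stripping the wrapping of that bond's
desolvation domain. Because neighbouring domains overlap along a helix,
stripping depresses ρ for adjacent bonds too; the stripped bond itself has
the minimum ρ and is the planted dehydron. The wrapping fixture instead
plants *exact* counts: lone carbon probes placed ≥ 0.5 Å inside or outside
the two-sphere boundary and ≥ 2.5 Å from all other atoms, so the expected
ρ is exactly the inside count.

The restrained-dimer generator is a Gaussian network at Cα level: springs
on residue pairs within 7 Å, plus explicit electrostatic-loop-to-
electrostatic-loop springs across the dimer interface, plus an optional
spring standing in for the Cys57–Cys146 disulfide (its removal emulates
the reduced state — an analogy, not chemistry). Fluctuations follow the
multivariate Gaussian with covariance T·K⁺ (pseudo-inverse after removing
the rigid mode); each Cartesian component is sampled independently and the
analytic per-residue RMSF √(3T·K⁺_ii) is returned alongside the frames for
oracle tests.

The restraint protocol requires a modelling decision. In a harmonic
network, adding restraint springs is a positive-semidefinite perturbation
and can only *decrease* every positional variance — pinning one loop
cannot, by itself, raise the partner loop's fluctuation. The observed
effect of an oligomer contact is contact *replacement*: the interface
displaces the loop's native cross-chain interactions even as it fixes the
loop in place. The generator therefore models a restraint as pinning the
selected residues (stiff springs to their reference positions, default
k = 100× the native spring) *and* deleting their springs to the other
chain (`restraint_replaces_contacts`, on by default). Under this protocol
the pinned loop's RMSF collapses (≳ 5×) while the partner loop's RMSF
strictly rises — the qualitative contrast restrained MD shows — and both
directions are asserted analytically and on sampled trajectories across
seeds and dimer sizes. Absolute fluctuation magnitudes are in units of the
arbitrary temperature scale and are not claimed to match any force field.

What the generators do not emulate: side-chain packing and anharmonicity,
explicit solvent and its timescales, real SOD1 topology (the chain trace
is a compact coarse helix, chosen only to give a connected contact
network), and sequence-dependent energetics. Passing tests therefore
demonstrate the correctness of the analysis machinery and the
linear-response direction of the restraint effect — not force-field-level
agreement with explicit-solvent simulations of SOD1.

## Problem sizes and determinism

The shipped study conditions use a 153-residue-per-chain dimer (306
network nodes), trajectories of 400–5000 frames, 1000-frame distance
series, and 100-fixture oracle sweeps; these sizes give sampling errors
well inside the asserted tolerances (e.g. sampled RMSF within 10% of
analytic at 5000 frames) while keeping any run to seconds. All randomness
flows through explicit integer seeds; identical inputs produce
byte-identical TSV/JSON reports, which the pipeline's manifest checksums
verify.

## Known limitations

- Frustration class labels for specific SOD1 contacts (e.g. whether
  Lys128–Ser134 is highly frustrated) depend on the energy function;
  with the shipped hydropathy table only the procedure, not those labels,
  is reproducible.
- The dehydron radius convention must be calibrated against a reference
  structure when absolute ρ values are to be compared across software.
- The change-point scan assumes step-like transitions separated by at
  least one dwell window.
- The GNM surrogate is isotropic and harmonic; it reproduces contrast
  directions, not magnitudes or timescales.
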