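# Methods

This note documents the models, conventions and design choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
numerical details that matter for reproducibility. Units are Å and ns
internally; conversions (cm²/s, kJ/mol, ps) happen only when reporting.

## Coordinate model and geometry

Systems are flat lists of atoms carrying residue identity, a segment class
(protein/lipid/ligand/solvent/ion) and an analysis *role* (protein heavy
atom, lipid tail carbon, lipid head group, ligand). Roles are assigned by an
explicit rule table over (residue name, atom name, element) — a pure
function, re-runnable at will; unknown residues get `other` plus a logged
warning rather than a silent guess. "Tail carbon" means the acyl-chain
carbons of the sn-1/sn-2 chains *excluding* the two ester carbonyl carbons,
since the hydrophobic chains are what nonpolar contact counting is meant to
capture; which carbons count is configurable (YAML rule table) because
reasonable conventions differ on the glycerol-adjacent positions.

Structure I/O goes through biotite (PDB and GRO; multi-model PDB for
trajectories with a declared frame spacing, default 0.01 ns). Author residue
numbering is preserved exactly — GRP1-PH constructs run 261–385, so reports
can name residues like H355 or A346 directly. Alternate locations resolve to
the highest occupancy.

Only orthorhombic periodic boxes are supported (the systems of interest are
rectangular slabs); triclinic input raises an explicit error. The
minimum-image displacement is `Δ − box·round(Δ/box)` per axis, which equals
the minimum over all images for orthorhombic cells.

## Membrane frame and docking

Leaflets are found from lipid head-group z coordinates: the splitting plane
is the mean head z (stored as the midplane), and each leaflet plane is the
mean z of the heads on its side. The membrane surface is treated as the
plane normal to +z — adequate for the planar slabs analysed here; curved or
undulating membranes are out of scope.

A vector's *tilt* is the signed angle between it and the membrane plane,
`asin(v̂·n̂)` in degrees, positive when the vector points along the outward
normal of the upper leaflet. Head-group placement finds a rigid rotation
giving the C1→C4 and C3→C5 ring vectors their target tilts. Two tilt
constraints leave a 3-DOF rotation under-determined: the solution set is a
one-parameter family under rotation about the normal, times a two-fold
chirality choice. We solve the target unit vectors in closed form (prescribed
z-components, preserved inter-vector angle), map by triad alignment, and pick
the family member with the smallest total rotation angle. That choice makes
the operation idempotent and near-identity on inputs that already satisfy the
targets; when the pair is not exactly achievable for the ring's internal
geometry a least-squares orientation is used and residuals above 5° raise.
Rotation is about the ring centroid, so all interatomic distances are
preserved to floating-point precision.

Grafting onto the bilayer translates the oriented complex so its ligand
phosphate lands on the host lipid's head-group phosphate, removes the host
head-group atoms, renumbers atoms uniquely, and reports steric clashes
(inter-part pairs under 1 Å) rather than resolving them — pose refinement is
the simulation engine's job, not this toolkit's.

## Contacts and hydrogen bonds

A nonpolar contact is a (lipid tail carbon, protein heavy atom) pair with
minimum-image distance strictly below the cutoff (default 4.0 Å). The strict
inequality is a measure-zero choice fixed for reproducibility. Counts are
per protein residue and a tail carbon may count against several residues.
The trajectory profile is the per-frame mean; the per-ps value divides that
mean by the frame spacing in ps (10 ps spacing ⇒ divide by 10). This
normalisation reads the 0–2 colouring scale as contacts per ps of sampling
interval: single-frame pair counts for a buried loop run well above 2, so a
raw per-frame average cannot be what such a scale shows. A `binary` switch
instead counts each (residue, tail carbon) combination at most once per
frame, since pair counts versus any-contact indicators is a genuine
ambiguity in how such profiles are reported.

Neighbor search uses a periodic KD-tree above 200 atoms and the direct
O(N²) distance matrix below; both paths are contract-tested to produce
identical counts, and the brute-force oracle in the test suite is the
reference for both.

Hydrogen bonds are geometric: donor–acceptor distance ≤ 3.5 Å and
donor–hydrogen–acceptor angle ≥ 150°, the common community defaults (both
configurable — no universal criterion exists). Donors and acceptors come
from atom-name rule tables restricted to N/O/S/F heavy atoms. The model
carries no bond list, so a donor's hydrogens are associated geometrically:
same residue, name starting with H, within 1.2 Å. A heavy-atom-only mode
applies the distance criterion alone (for hydrogen-free models) and flags
its records. Occupancy is the fraction of frames in which a given
(donor atom, acceptor atom) pair bonds; the residue inventory lists residues
with any pair at occupancy ≥ 0.10 against a chosen partner (e.g. the
ligand).

## Lateral diffusion

Protein in-plane motion is measured relative to the membrane: per frame, the
xy difference of the mass-weighted centres of mass of the mobile and
reference groups, which cancels rigid drift exactly. The 2D MSD averages
over all time origins (sliding window) — the standard variance-reduction
choice — computed with the FFT autocorrelation identity so 10⁴-frame series
are cheap; a direct double-loop oracle pins the implementation to 10⁻⁹.
D is the least-squares MSD slope over a lag window divided by 4, converted
at 1 Å²/ns = 10⁻⁷ cm²/s. The default window is the first half of the
available lags, mirroring the practice of fitting the early, approximately
linear regime (the first 50 ns of a 100 ns trajectory). The quoted
uncertainty is the half-spread of D refit on the two halves of the series —
a block estimate, labelled as such in output since reported ± values for
simulated D rarely state their method.

## Steered pulls and energies

The pull protocol is a harmonic spring (default k = 500 pN/Å) whose anchor
retreats along +z at constant speed; the two standard settings, 0.5 Å/ns
over 80 ns and 1.0 Å/ns over 40 ns, both retract 40 Å. Spring force is
k·(anchor − COM), positive toward the anchor; work is the trapezoidal
integral of force over *anchor* displacement, reported in pN·Å and kJ/mol
(1 pN·Å = 0.06022 kJ/mol).

Group–group interaction energies are short-range pairwise sums over
inter-group pairs within the cutoff (default 10 Å, minimum-image):
Coulomb f·qᵢqⱼ/(ε_r·r) with f = 1389.35 kJ·Å·mol⁻¹·e⁻² (vacuum; dielectric
configurable) and 12-6 Lennard-Jones with geometric combination rules
(GROMOS convention; Lorentz–Berthelot selectable). No reciprocal-space/PME
reconstruction is attempted: the decomposition mirrors the *short-range
components* of an engine's energy terms, which is the quantity such pull
analyses plot. Energies are pairwise inter-group only — no intra-group
terms. Nonbonded parameters (charge, σ, ε per atom) are user-supplied, keyed
by residue+atom name with an atom-name fallback.

Lipid extraction is classified from the lipid COM height above the upper
leaflet plane: fully extracted above 10 Å, partially extracted in (4, 10] Å,
else in the bilayer. The thresholds are heuristics — extraction is usually
shown, not quantified — so they are parameters and are echoed with every
result.

## NMR chemical-shift perturbation

Combined amide CSP is √(Δδ_H² + (α·Δδ_N)²) with α = 0.2, the customary
weighting for the larger ¹⁵N dispersion; α is configurable because published
normalisations vary. Only residues present in both conditions enter the
statistics; unmatched residues are listed as missing, never silently
dropped. Significance uses the dataset's own mean + 1·SD (population SD,
strict >, recomputed per dataset); the large/medium split at mean + 2·SD
mirrors two-tier structure colouring and is a convention of this package.
All-equal input (SD = 0) yields nothing significant. The pH-series
comparison flags, per residue, whether the combined CSP grows strictly at
every step down in pH. Micelle stoichiometry divides detergent monomer
concentration by the aggregation number (56 for DPC), so 286 mM detergent is
5.1 mM micellar.

## Monolayer critical pressure

π_c is the x-intercept of the unweighted least-squares line Δπ = a + b·π₀ —
the universal convention for monolayer penetration data; the method string
travels with every fit. Replicate π₀ values are averaged before fitting. A
non-negative slope means no extrapolable penetration limit and raises.
Construct comparison ranks fitted π_c and reports differences against the
wild type.

## Synthetic generators

The generators produce inputs with *known ground truth*, which is what the
test suite and the acceptance script measure against. Defaults are the study
conditions: pull spring 500 pN/Å at 0.5 Å/ns, frame spacing 10 ps, contact
cutoff 4 Å, head-group tilts (+40°, −17.5°), wild-type π_c 28 mN/m with
mutant series near 23.5, diffusion at 0.3 Å²/ns (3.0 × 10⁻⁸ cm²/s), 14
perturbed residues among 120 with effects 5× background noise
(0.10 ppm vs 0.02 ppm ¹H), monolayer noise 0.2 mN/m over six points.

Pseudo-lipids are bead chains — one head phosphate bead plus 8 tail-carbon
beads on a jittered grid at ±20 Å — not chemically complete POPC: the
contact, extraction and leaflet analyses consume roles and geometry only.
Bilayers are static; protein thermal motion is isotropic Gaussian jitter;
Brownian walks are free (no confinement, no anomalous exponent); pull traces
follow a quasi-static force balance with a single sharp rupture. Passing
tests therefore demonstrate correctness of the *analysis operators* under
controlled truth, not fidelity of any molecular mechanics: real trajectories
bring correlated motion, undulations and force fluctuations these fixtures
deliberately omit. Problem sizes (e.g. 100 walkers × 10⁴ steps for
diffusion recovery, ≤ 32-lipid leaflets, 10–30-frame trajectories) were
chosen as the smallest at which the estimators' statistical claims are
comfortably testable.

Each generator consumes one `numpy` `default_rng(seed)`; there is no global
random state, identical seeds give bit-identical output, and the ground
truth is serialized with every dataset.

## Known limitations

Planar-membrane assumption throughout; orthorhombic boxes only; no
energy-based docking or pose sampling; no PMF/Jarzynski free-energy
estimation from pull work; H-bond hydrogen association is geometric rather
than topological; no anomalous-diffusion analysis; no titration K_d fitting
from CSP magnitudes.
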