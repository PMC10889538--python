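# Methods

This note documents the models, conventions and numerical choices the
package implements, what the synthetic generators do and do not
emulate, and the known limitations.

## Data model

An `Ensemble` is an ordered stack of conformations over one `Topology`
(fixed atom order, 1-based biological residue numbering, named regions
such as `L-loop` or `TM1`–`TM4`).  Frames carry a time stamp in ps and
a source label, so ensembles from several proteins can be concatenated
while remaining separable.  Cross-protein merges require identical
atom sets; since point mutants differ in side chains, merged analyses
operate on backbone or Cα selections — `Ensemble.subset_atoms` before
`concatenate`.  Frames without explicit time stamps are assigned
`index × stride`.

## Superposition and descriptors

Fitting is unweighted least squares (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) on a stated atom
selection, applied to all atoms.  Collinear or sub-3-atom selections
are rejected because the optimal rotation is then under-determined.

- **RMSD** is reported after the optimal fit on the selection.  Inside
  the reference-based clustering, however, RMSD is computed *without*
  refit in the shared frame of a pre-fitted ensemble: the intended use
  fits on the stable domain and then compares the mobile region, so
  rigid-body motion of the scaffold is removed once, not per pair.
- **RMSF** fits all frames to frame 0 on the selection and measures
  fluctuation about the ensemble mean,
  `RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩)` (population mean over frames).
- **Radius of gyration** is mass-weighted over non-hydrogen atoms by
  default, measured from the selection's centre of mass.  The analysed
  region is a parameter: whole protein or a named region.
- **Probability densities** use fixed-width histograms (0.1 Å default
  bins) rather than kernel smoothing so that outputs are deterministic;
  smooth published curves are a rendering choice, not a statistic.
- **Helix axes** are the line through the first and last Cα of a helix
  range.  For display export the endpoints are elongated by 25 % per
  end (+50 % total); the stored direction is the unextended unit
  vector.

## Contacts

Hydrogen bonds follow the geometric criterion: donor and acceptor are
N/O heavy atoms, D⋯A ≤ 3.6 Å (boundary inclusive), pseudo-valent angle
at the hydrogen strictly > 90°.  Donors must carry an explicit
hydrogen (attached within 1.25 Å); there is no distance-only fallback —
a donor without a resolvable H is skipped.  Covalently bound D–A pairs
(< 1.8 Å) are excluded.  Occurrence aggregates events per (D, A) pair
over all hydrogens of the donor; pairs with frequency ≥ 0.6 are
retained.  The strength scale maps the D⋯A distance onto [0, 1] over
2.6–3.6 Å with 0 the strongest (shortest) end.

Hydrophobic contacts are side-chain carbon pairs (CB and beyond; never
backbone C/CA, hence glycine never qualifies) of residues in
{ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO}, closest C–C ≤ 4 Å, with a
sequence separation of at least 2 to exclude trivial neighbours.  The
residue set is configurable.

Salt bridges are defined structurally as the subset of detected
H-bonds joining a basic side-chain nitrogen (Arg NE/NH1/NH2, Lys NZ,
His ND1/NE2) to a carboxylate oxygen (Asp OD1/OD2, Glu OE1/OE2) in
either donor/acceptor direction.  This is a package convention — the
criterion is not standardised — and is deliberately a relabelling, not
an independent detector.

## Secondary structure

DSSP is re-implemented rather than shelled out, keeping the pipeline
self-contained: backbone H-bonds are scored with the Kabsch–Sander
electrostatic energy `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN)` kcal/mol and accepted below −0.5 kcal/mol; helices come from
doubled i→i+3/4/5 turns (priority H, then strand ladders, then G, I,
then turns and bends); amide hydrogens are reconstructed at 1.01 Å
from N anti-bisecting C(prev)–N–Cα when absent; chain breaks (peptide
C–N > 2.5 Å) split the turn patterns.  The tests cross-check the
assignment against the DSSP shipped with mdtraj on identical
coordinates; that library is an oracle only, never the implementation.
π-bulge refinements and polyproline-II extensions of DSSP 4 are out of
scope.

The 8-letter alphabet reduces as H→α, G→3₁₀, I→π, E→strand, and
{B, T, S, C}→none.  Ensemble clustering represents each conformation
as the set of (residue, reduced letter) pairs with letter ≠ none;
pairwise dissimilarity is the Jaccard distance (empty∪empty → 0);
strand letters participate in the sets.  Complete-linkage trees are cut
at every pruning distance in {0.05, …, 1.00}; the silhouette score on
the precomputed distances selects the cut, ties resolved toward the
smaller distance (finest clustering).  Identical assignments collapse
to one cluster with an undefined (not zero) silhouette.

## RMSD clustering

The ensemble-based procedure: (i) pick a random remaining frame as a
reference and remove every frame within the cutoff r on the selection;
repeat until the ensemble is empty — references end up pairwise > r
apart; (ii) assign every frame to its nearest reference, leaving
frames farther than r from all references unassigned, so coverage can
be below 1.  The random choice is controlled by an explicit seed;
equidistant assignments break toward the earlier reference; clusters
are renamed C1, C2, … by population.  The cutoff sweep covers
2.4–7.0 Å in 0.2 Å steps with r = 4.0 Å flagged as the operating
point.  Medoids are exhaustive up to 2000 members and subsampled (with
a seed) above.  Whether the assignment phase should be
nearest-reference or first-within-r is ambiguous in the literature the
procedure derives from; nearest-reference is implemented.

## PCA, correlation, landscape

PCA fits all frames to their average iteratively (fit, re-average,
stop at ≤ 1e-6 Å mean change or 10 iterations), then takes the SVD of
the centred F × 3N matrix; eigenvalue k is s_k²/(F−1).  Two selection
presets mirror common practice: full backbone (N, H, Cα, C, O) for a
single protein and Cα-only for cross-protein merges (the default
there).  Terminal regions can be excluded through ordinary selection
filters; nothing is hard-coded.  A `fit=False` path exists for
pre-fitted coordinates; note that for finite displacements the rigid
fit is slightly non-linear, so a mathematically rank-1 displacement
field explains exactly 100 % of the variance only on the unfitted
path (99.9 %+ after fitting).  The trace identity Σλ = Σ RMSF² is
exact when both sides use the same sampling convention; the tests use
F−1 on both sides, while the reported RMSF uses the population mean
(the two differ by F/(F−1)).

Cross-correlation is the normalised covariance of atomic displacement
vectors after fitting, `C_ij = ⟨Δr_i·Δr_j⟩/sqrt(⟨Δr_i²⟩⟨Δr_j²⟩)`, on
Cα atoms by default; zero-variance atoms get zero rows with a unit
diagonal and a warning.  This is the trajectory-based correlation; an
elastic-network variant computed from a single average structure is a
different estimator and is not emulated.

The free-energy landscape Boltzmann-inverts a k-nearest-neighbour
density on (PC1, PC2): `density ∝ k/(n·π·d_k²)` evaluated on a regular
grid (100×100 over the projection range + 5 % margin), normalised over
nodes, then `ΔG = −k_B·T·ln(P/P_max)` with k_B = 1.9872e-3
kcal/(mol·K) and T defaulting to the 310 K simulation temperature.
The landscape minimum is exactly 0 by construction.  k defaults to
⌈√n⌉ — the standard bias/variance compromise for kNN density — and is
configurable.  Wells are grid local minima with steepest-descent
(watershed) basins on the 8-neighbourhood; minima whose separating
saddle lies less than `min_barrier` (default 0.5 kcal/mol) above the
shallower minimum are merged into the deeper one, which absorbs the
sampling noise of the kNN estimate (~k_B·T/√k).  Wells are labelled
W1, W2, … by increasing minimum ΔG; compositions are percentages of
member frames per source and sum to 100 per well.

## Pockets

The cavity detector works on a regular grid (0.5 Å default spacing):
a node is cavity when (a) a 1.4 Å probe centred there clears every
atom's van der Waals radius (C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20 Å), and (b) it is buried — of 14 deterministic rays (6 axial +
8 diagonal), at least 9 strike protein within 15 Å.  The burial
parameters were chosen to pass the analytic spherical-shell suite and
are configurable.  This grid/ray design replaces alpha-sphere (Voronoi)
pocket machinery deliberately: it is simpler, deterministic and
testable against closed-form cavity volumes, so outputs are comparable
in kind (volumes, frequency maps, lining residues) but not numerically
identical to alpha-sphere tools.  Grids beyond ~4M nodes are coarsened
with a warning.

Ensemble tracking superposes frames first (grid comparability), builds
the per-node cavity frequency, thresholds at an isovalue (default 0.5)
and labels 26-connected components P1, P2, … by decreasing mean
per-frame volume.  Per-frame volumes are cavity-node counts inside the
component region times the node volume; zero frames are legitimate for
cryptic pockets.  Lining residues have a heavy atom within 4 Å of a
pocket node; an arginine is "inward" when Cα→CZ projects positively
onto Cα→(pocket centroid).  The lining hydrophobicity score is the
mean Kyte–Doolittle hydropathy of the lining residues (shipped as a
fixed table and named in the output); pocket-tool-specific
hydrophobicity scores on other scales are not reproduced.

## Synthetic generators

The generators fabricate statistical structure, not physics — no force
fields, solvent or thermostats:

- **Ideal helices** from canonical dihedrals α (−57°, −47°),
  3₁₀ (−49°, −26°), π (−57°, −70°), built by NeRF chain extension with
  idealised bond lengths/angles and explicit amide hydrogens so the
  H-bond angle criterion is computable.  The α and 3₁₀ rises come out
  within 5 % of the textbook 1.5/2.0 Å; the π dihedral convention
  adopted here yields a rise of ≈ 1.09 Å against a textbook 1.15 Å
  (conventions for π vary), so the π helix is validated through its
  i→i+5 H-bond pattern instead.
- **Two-domain toy**: a bundle of ideal α-helices (antiparallel, on a
  circle of 8 Å radius, hydrophobic sequence) plus an irregular coil
  loop placed above it; regions TM1…TMn and L-loop are registered.
  The default dimensions (4 helices, 45-residue loop) mirror a
  four-helix membrane scaffold with a long disordered luminal loop.
- **Well mixtures**: frames drawn i.i.d. from Cartesian Gaussian wells
  with stated populations; perturbation can be restricted to a region
  (e.g. the loop) to mimic quasi-independent domain dynamics.  Same
  seed ⇒ bitwise identical output.
- **Cavity shells**: Fibonacci-sphere carbon shells at
  `r + vdW + probe` so the probe-accessible interior has exactly the
  requested radius; the analytic volume 4/3·π·r³ is recorded.  A
  too-sparse shell (mean spacing above the blocking radius) is
  rejected with a diagnostic.

What passing tests therefore show: the estimators recover *planted*
populations, volumes, folding patterns and energy differences under
i.i.d. Gaussian sampling.  What they do not show: behaviour under
correlated (autocorrelated-in-time) sampling, anharmonic wells,
force-field artefacts or solvent-mediated contacts — properties of
real MD data that no desk-scale synthetic ensemble reproduces.

## Pipeline and determinism

`run_dynasome` chains stride → fit → descriptors → contacts → SS (+
clustering) → RMSD clustering (+ sweep) → PCA (+ projections,
porcupine, correlation) → landscape (+ wells, composition);
`run_pocketome` runs the frequency-map tracker.  Every artefact is a
CSV/JSON file listed in `manifest.json` with its producing stage and
parameters.  All randomness flows from the config seed; reruns with
the same config are byte-identical (timings go to stderr, never into
artefacts).  The default synthetic suite (3 sources × 60 frames,
697-atom toy; 12-frame pocket ensemble) keeps a full run around a
minute on one CPU; the acceptance script's problem sizes (n = 3000
frames for clustering recovery, n = 10⁴ points for the landscape, 10
and 5 seed replicates) are chosen to make the binomial/kNN error bands
comfortably tighter than the tested tolerances.

## Known limitations

- PDB I/O only (plus a columnar text trajectory); binary MD formats
  are out of scope.
- The H-bond criterion is purely geometric; adjacent-residue N–H⋯N
  pairs that satisfy it are reported, as the criterion admits them.
- Strand (E) assignment implements minimal ladder detection; sheet
  topology labelling and β-bulges are not assigned.
- Landscapes are 2-D only; no reweighting for biased sampling.
- The pocket detector's absolute volumes depend mildly on grid
  registration (± a node shell); tests budget 15 % for this.
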