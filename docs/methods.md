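# Methods

This note records the models implemented in `dimerscope`, the parameters
that matter, the numerical choices made where the design was genuinely
open, and what the synthetic benchmark does and does not establish.

## Dihedral-angle PCA

Cartesian PCA of a flexible dimer mixes internal motion with overall
tumbling and suffers from the periodicity of angles; dPCA instead analyzes
the backbone torsions γₙ (the φ and ψ of each residue) through the
embedding q = (cos γ₁, sin γ₁, …, cos γ_N, sin γ_N). The model fitted by
`dpca.fit` is the eigendecomposition of the covariance matrix of q
(mean-centered, unbiased 1/(T−1) normalization); projections are the
centered data times the eigenvectors.

Choices:

* **No mass weighting.** The embedded coordinates are dimensionless
  direction cosines; masses have no place in the dihedral formulation.
* **Covariance, not correlation.** All 2N coordinates live on the same
  [−1, 1] scale, so rescaling to unit variance would only amplify
  near-frozen angles.
* **Sign convention.** Eigenvector signs are arbitrary in exact
  arithmetic and backend-dependent in practice; each eigenvector is
  flipped so its largest-magnitude entry is positive, making projections
  reproducible across LAPACK builds.
* **Terminal and broken angles are dropped, not imputed.** A residue pair
  whose C–N distance exceeds 2.0 Å in the first frame is treated as a
  chain break and the spanning φ/ψ excluded with a warning; the 2N
  bookkeeping always refers to retained angles. Component indices are
  1-based in every user-facing API (PC1, PC2).
* **Whole-dimer fit with per-chain reporting.** The dPCA default treats
  both chains' angles as one coordinate set (inter-chain concerted motion
  is visible), while Δₙ(k) profiles carry chain labels so per-chain
  reading remains possible; a chain filter restricts the fit when wanted.

The per-angle contribution Δₙ(k) = v₂ₙ₋₁(k)² + v₂ₙ(k)² sums to exactly 1
over n for every component because the eigenvectors are unit vectors —
this identity is used as a machine-precision self-check throughout the
tests and the acceptance script.

## Free-energy landscape and clustering

ρ(V₁, V₂) is a plain 2-D histogram over the bounding box of the first two
projections, padded by 1 % per side so extreme points fall strictly inside
the outer bins; counts are normalized by T·(cell area). The landscape is
ΔG = −[ln ρ − ln ρ_max] in units of k_BT (an option multiplies by
k_B·T with k_B = 0.0019872 kcal/(mol·K), default T = 310 K, for absolute
units). Cells with ρ = 0 are masked rather than given an arbitrary large
value; ΔG = 0 exactly at the density maximum because the two logarithms
cancel bitwise.

* **Grid.** 64×64 bins by default — fine enough to separate metastable
  states at T ≳ 10³ frames, coarse enough that the densest cells hold tens
  of frames.
* **Seed detection on a smoothed field.** A raw histogram has a
  Poisson-noise local maximum every few cells. Seeds and hill-climbing
  topography therefore use the density smoothed with a Gaussian of
  σ = 2 grid cells (`smooth_sigma`, 0 disables). Local maxima below
  `min_density_fraction` (default 0.05) of the smoothed maximum never
  seed a cluster.
* **Persistence pruning.** Watershed basins whose peak rises less than
  `prominence_fraction` (default 0.2) of the global smoothed maximum
  above their highest connecting saddle are merged into the neighbor
  across that saddle. This collapses shoulders of a single mode while
  preserving genuinely separated modes; a unimodal cloud yields exactly
  one cluster, well-separated modes one cluster each.
* **Ranking and ties.** Clusters are ranked by raw peak density, so
  cluster 1 contains the global density maximum; equal-density adjacent
  maxima merge into one plateau seed.

Frames are labelled by the cluster of their histogram cell; reusing a
fitted grid on foreign data that falls outside the edges is an error.

## Superposition, RMSD, RMSF

Superposition is least-squares rigid (Kabsch via rotation alignment);
reflections are never returned. RMSD series use the same atom selection
(Cα by default) for fitting and measurement, against a chosen reference
frame. RMSF first aligns all frames to frame 0, computes the mean
structure, re-aligns to that mean (two passes — further iterations change
results below numerical noise for trajectories of this kind), then takes
the per-atom RMS deviation from the mean.

## Hydrogen-bond monitoring

The monitored quantity is a plain distance trace between two named atoms
(`chain:res:name`). Two criterion styles coexist because practice mixes
them: explicit hydrogen–acceptor pairs (e.g. Asn HD21 to Thr OG1) use a
2.5 Å default cutoff, heavy donor–acceptor pairs (ND2 to O) 3.5 Å. No
angular criterion is applied — occupancy is the fraction of frames within
the distance cutoff.

## SASA

Shrake–Rupley with Bondi radii (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å),
probe 1.4 Å, 960 quadrature points by default — NACCESS-comparable
settings. The quadrature layout is a deterministic golden spiral (no RNG),
expressed per atom in a **local frame built from the atom's nearest
neighbors**. This makes SASA exactly covariant under rigid motion of the
molecule (the points rotate with it) and makes the per-atom SASA of two
far-apart groups bitwise identical whether computed separately or
together — so the buried-area difference ½[SASA(A)+SASA(B)−SASA(AB)]
vanishes exactly for non-interacting chains instead of carrying ±few Å² of
quadrature noise. Quadrature error for a single sphere is < 2 % at 960
points (checked against 4πr² analytically). Interface snapshots default to
240 points: the buried area there is a per-snapshot summary, not a
convergence study.

## Interface detection, contact typing, hot spots

Interface membership is transparent and distance-based: any residue with a
heavy atom within 5.0 Å of the other chain. (Server-style definitions —
PISA, PDBsum, NACCESS — differ among themselves; one declared in-house
definition is testable against generator ground truth. A ΔSASA-based
membership can be obtained from the same SASA machinery if burial is
preferred.) Contact typing is priority-ordered and unique per pair:

1. *hydrogen bond* — both atoms N/O/S, one donor and one acceptor by a
   fixed per-residue table (element-based fallback for non-standard
   residues, no protonation inference), heavy-atom distance ≤ 3.5 Å; or an
   explicit donor hydrogen within 2.5 Å of an acceptor;
2. *carbon–hydrogen* — carbon vs N/O at 3.5–3.8 Å, or a carbon-attached
   hydrogen within 3.0 Å of an acceptor (the weak C–H···O class);
3. *van der Waals* — any remaining heavy-atom pair ≤ 4.5 Å.

Hot spots are defined by snapshot consensus: the chainwise intersection of
interface residue sets over all analyzed snapshots, which is monotone
non-increasing as snapshots are added. Snapshot times are nearest-frame
matched with a warning when the gap exceeds half the frame spacing. The
snapshot list is a user input; a seven-time series spanning the run is the
documented example. Glycan contacts are typed with the same rules and
labelled intra-/inter-chain relative to the glycan's own chain.

Stabilization pseudo-energies per residue (PPCheck-style kJ/mol numbers)
are deliberately not computed: they have no re-derivable definition, so
interfaces are characterized by counts, types, distances and buried areas
instead.

## Synthetic trajectory generator

The generator emulates the statistical structure of a metastable dimer
trajectory, not its physics:

* **States.** A hidden Markov chain over K conformational states
  (default K = 2: α-helical (−57°, −47°) vs β-extended (−120°, 130°)
  basins for every residue; 0.95/0.05 transition rows; initial state 0).
* **Angles.** Per frame, each (φ, ψ) is drawn von Mises around the state
  mean with concentration κ (default 20, ≈ 13° sd) — the natural circular
  family with closed-form sampling.
* **Backbone.** Ideal-geometry N/CA/C placement by sequential NeRF with
  bond lengths 1.46/1.53/1.33 Å, angles 111°/117°/121°, ω = 180°.
  Recomputing dihedrals from built coordinates returns the inputs to
  ~1e-15 rad, which anchors the dPCA inverse-consistency tests.
* **Dimer assembly.** Chain B is rigidly placed per frame so each contact
  pair (`chain:res:name` on each side) sits at its target distance plus
  Gaussian noise. One pair is solved exactly (the orientation points B's
  centroid away from chain A, then the translation is exact); several
  pairs are solved by least squares over rotation+translation on the
  distance residuals, seeded by a correspondence fit and retried from
  random orientations; residuals above 0.5 Å raise an infeasibility
  error. Contacts can be transient (`active_fraction` < 1 releases the
  pair to target + 10 Å for the remaining frames), giving a known
  persistent/transient split for hot-spot tests.
* **Decorations.** Named donor/acceptor pseudo-atoms sit 1.5 Å off a
  residue's CA along the Cβ-like bisector; a glycan site attaches a
  5-heavy-atom GlcNAc-like `NAG` pseudo-residue 2.9 Å off the anchor CA,
  on the anchor's own chain.
* **Ground truth is measured, not asserted**: interface residues per frame
  and H-bond-satisfying frames are computed from the final coordinates,
  so truth and geometry cannot disagree. Same seed ⇒ bit-identical output.

What passing the synthetic benchmark shows: the analysis chain recovers
designed metastable structure, interfaces and contacts from coordinates
alone. What it does not show: behavior on real ensembles — the generator
has no side chains beyond stand-ins, no solvent, no realistic Ramachandran
coupling between neighboring residues, and its inter-chain pose is rigid
per frame rather than diffusive. Conclusions about real β1/β2 dimers
require real trajectories.

## Problem sizes

Default test and acceptance workloads are desk-scale by design: 2000-frame
single-chain series for state recovery, 60–100-frame dimers for interface
work, 64×64 landscape grids, 240–960 SASA points. These sizes hold every
statistical check at ≥ 3σ margins while the full suite runs in well under
a minute.

## Known limitations

* The multi-model PDB reader keeps the first alternate location and
  requires identical atom order across models (written files comply).
* Donor/acceptor tables cover the 20 standard residues plus the GlcNAc
  stand-in; exotic residues fall back to element-based rules.
* The carbon–hydrogen contact class uses distance windows only; no C–H···O
  angle term.
* `rmsf` assumes the selection is large enough to pin the alignment; a
  selection dominated by the mobile atoms themselves absorbs part of the
  motion into the fit, as in any RMSF implementation.
* Cluster counts depend on `smooth_sigma` and `prominence_fraction` when
  modes overlap strongly; the defaults favor few, heavily populated
  clusters over fragmenting noise.
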