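# dimerscope

Analysis toolkit for molecular-dynamics trajectories of **two-chain protein
dimers** — in particular adhesion-style *trans*-dimers such as the Na⁺,K⁺-ATPase
β-subunit ectodomain pairs (β1–β1 vs β2–β2), where the questions are: which
conformational states does the dimer visit, which residues form the
protein–protein interface, which of them persist as *hot spots*, and which
hydrogen bonds and glycan contacts hold the interface together?

Because production MD trajectories are rarely deposited, the package ships a
first-class **synthetic trajectory generator** with known ground truth, so
every stage of the analysis can be validated end to end.

## What it computes

* **Dihedral-angle PCA (dPCA).** Backbone torsions γₙ ∈ {φ, ψ} are embedded as
  q = (cos γ₁, sin γ₁, …, cos γ_N, sin γ_N) to remove angular periodicity.
  The covariance matrix of q is diagonalized; the k-th principal component of
  a frame is V_k = v(k)·(q − ⟨q⟩). The per-angle contribution

  Δₙ(k) = v₂ₙ₋₁(k)² + v₂ₙ(k)², with Σₙ Δₙ(k) = 1,

  localizes component k on the sequence.
* **Free-energy landscape.** With ρ(V₁,V₂) estimated by a 2-D histogram,
  ΔG(V₁,V₂) = −k_BT [ln ρ − ln ρ_max], so ΔG = 0 exactly in the most
  populated cell. Grid basins (local maxima + steepest-ascent hill climbing,
  persistence-pruned) define conformational clusters; cluster 1 holds the
  global density maximum.
* **Structure metrics.** Kabsch superposition (proper rotations only),
  Cα RMSD series, iteratively aligned RMSF, atom-pair distance traces with
  distance-only H-bond criteria (2.5 Å H–acceptor / 3.5 Å heavy-atom), and
  Shrake–Rupley SASA on a deterministic golden-spiral quadrature.
* **Interfaces.** Interface residues by a 5 Å heavy-atom cutoff, contacts
  typed hydrogen-bond / carbon–hydrogen / van-der-Waals with fixed priority,
  buried area ½[SASA(A)+SASA(B)−SASA(AB)], per-chain interface percentages,
  snapshot-consensus **hot spots** (residues present in every snapshot), and
  glycan–protein contact tables labelled intra-/inter-chain.
* **Sequence identity.** Needleman–Wunsch global identity (BLOSUM62,
  affine gaps) for model-vs-template validation.
* **Synthetic data.** Von Mises hidden-Markov dihedral dynamics over K
  metastable states, ideal-geometry backbone rebuilt by internal-coordinate
  (NeRF) placement, rigid per-frame placement of chain B to realize target
  contact distances (exact for one contact, least-squares for several),
  optional donor/acceptor pseudo-atoms and GlcNAc-like glycan stand-ins.

## Worked example

```bash
python examples/03_free_energy_landscape.py
```

```
Delta G at the densest cell: 0.000 kBT (the landscape anchor)
highest free energy among populated cells: 3.58 kBT
clusters found: 2 (ranked by peak density)
  cluster 1: 929 frames
  cluster 2: 1071 frames
hidden-state recovery (permutation-aligned): 100.0%
```

A 2000-frame two-state trajectory (κ = 20, 5 % switching) is generated,
projected onto its first two dPCA components and histogrammed: the free
energy is 0 in the most populated cell by construction, the grid clustering
finds exactly the two metastable states, and assigning each frame to its
cluster recovers the hidden Markov labels perfectly. The other scripts in
`examples/` demonstrate the generator, dPCA contributions, RMSD/RMSF and
H-bond traces, interface hot spots with glycan typing, and sequence identity.

The same pipelines are scriptable from the shell:

```bash
dimerscope simulate --n-res 20 --n-frames 200 --out traj.pdb --truth truth.json
dimerscope dpca traj.pdb --out d
dimerscope landscape d_projections.tsv --out l
dimerscope interface traj.pdb --chains A,B --out i
dimerscope report --config run.cfg
```

## Layout

```
src/dimerscope/      trajectory_io, synthetic_data, dpca, landscape,
                     structure_metrics, interface, seq_utils, cli
examples/            one short narrative script per capability
tests/               pytest suite incl. end-to-end acceptance checks
scripts/acceptance.py
docs/methods.md      models, parameters, numerical choices, limitations
```
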