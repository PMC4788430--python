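# tailensemble

Expanded-ensemble lambda dynamics on a coarse-grained "tail on scaffold"
model, canonical reweighting, and a structural-ensemble statistics suite.

A flexible, positively charged bead chain (the *tail*) is tethered to a
rigid, negatively charged scaffold that mimics wrapped double-stranded
DNA. An extra dynamic variable λ scales the tail's energy terms
(λ² intra-tail, λ tail–environment) and diffuses jointly with the
coordinates under Langevin dynamics. An adaptive umbrella bias
RT·ln P(λ) flattens the λ marginal so the sampler random-walks across
λ ∈ [0.6, 1.03]; importance reweighting then reconstructs the canonical
ensemble at λ = 1. Statistics (means ± standard errors) always combine
many short independent runs at the run level ("trivial trajectory
parallelization", TTP).

The analysis suite operates on the coarse-grained ensembles and on
all-atom PDB structures:

* Shrake–Rupley solvent-accessible surface area (SASA) and the contact
  surface area (CSA) between two groups (area one group buries on the
  other), with the radii C 1.7 / N 1.625 / O 1.48 / P 1.87 Å, probe
  1.4 Å, hydrogens excluded;
* radius of gyration, Kabsch superposition, weighted 3D density grids
  and difference maps (text voxel maps + OpenDX export);
* per-position contact probabilities along the scaffold, side-chain
  terminal-atom DNA-contact and solvent-exposure ratios;
* backbone φ/ψ dihedrals and a dihedral-window helix assignment
  (φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°], runs of ≥ 4 residues);
* site–site distance distributions.

## Command-line pipeline

Stage-wise, each stage writing a manifest (config hash, input hashes,
seeds, package version) and refusing to run on missing upstream outputs
(exit codes: 0 ok, 2 config error, 3 stale/missing input, 4 numerical
failure):

```bash
tailensemble build   --config run.yaml --workdir work        # system + starting conformations
tailensemble build   --config run.yaml --workdir work-ac --acetylate 14
tailensemble adapt   --config run.yaml --workdir work        # estimate the umbrella bias
tailensemble sample  --config run.yaml --workdir work        # TTP production runs
tailensemble reweight --config run.yaml --workdir work       # canonical frame weights + ESS
tailensemble analyze --config run.yaml --workdir work --compare work-ac
```

`analyze` emits tidy TSV tables (CSA and Rg summaries with run-level
standard errors, Rg histogram, per-position contact, pair distances) and
tail density grids, plus an unacetylated−acetylated difference map when
`--compare` is given. Every table header echoes the exact radii,
thresholds and seeds used.

One-shot CSA on a deposited structure:

```bash
tailensemble csa-pdb --pdb data/1KX5.pdb \
    --tail "chain A and resid 1-40 and heavy" --dna "nucleic and heavy"
```

The configuration file is YAML with sections `system`, `forcefield`,
`sampler`, `adapt`, `analysis` plus `acetylate_positions`, `n_runs`,
`seed`; all fields default sensibly (see `tailensemble/config.py`).

## Units

Lengths in Å, energies in kcal/mol, temperature in K, charges in units
of the elementary charge; R = 1.98720×10⁻³ kcal/mol/K, Coulomb constant
332.0636 kcal·Å/(mol·e²). Time is an internal MD unit (bead mass 1).
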