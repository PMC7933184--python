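# glycocover

Quantitative analysis of how N-glycans shield ligand binding sites on
glycoprotein surfaces, with companion NMR titration analysis.

Cell-surface receptors such as CD44 carry bulky, flexible N-glycans that can
drape over the very surface patches their ligands need. Whether a given
binding mode survives glycosylation is a quantitative question: how often is
each binding-epitope residue physically covered by glycan atoms, and how
does that fold up into a per-mode obstruction score? `glycocover` answers
this for molecular-dynamics trajectories of glycosylated receptors and
cross-references the picture against HSQC chemical-shift-perturbation data —
the toolset a structural-glycobiology group needs when asking which binding
mode a glycoform leaves open.

## What it computes

**Per-residue glycan coverage.** For receptor residue *res*, the contact
fraction

    C_res = (# frames with min distance(res, glycans) < 0.3 nm) / n_frames

where the minimum runs over all atom pairs and uses the minimum-image
convention in periodic (orthorhombic) boxes.

**Binding-mode coverage.** Given a *footprint* — per-residue weights
`w_res ∈ [0,1]` describing how strongly the ligand contacts each residue in
a binding mode — the per-replica mode coverage is the weighted mean

    C_mode = Σ_res w_res · C_res / Σ_res w_res ,

reported as a replica average ± sample standard error. It is invariant to
uniform weight rescaling and bounded by the min/max residue coverage.
Example membership footprints for the CD44 hyaluronan-binding domain
(crystallographic, parallel, and upright modes; key arginines) ship with
the package.

**Also:** inter-entity atom-contact maps (0.6 nm cutoff), replica-averaged
per-residue surface distance maps (display-clamped to 0.3–1.5 nm),
ligand association/dissociation events by two-threshold hysteresis
(0.3 nm on / 0.5 nm off, 1 ns dwell filter), Shrake–Rupley SASA and buried
interface areas `(SASA_A + SASA_B − SASA_AB)/2`, and NMR analysis:
combined CSP `√(ΔδH² + (0.2·ΔδN)²)`, the minimal-shift method for
unassigned bound spectra, and instant/gradual/disappearance titration
classification.

Every stage is validated against synthetic trajectories and peak lists with
*planted* ground truth (exact frame-count constructions), generated by the
`glycocover.synthetic` module.

## Worked example

```bash
python examples/01_mode_coverage.py
```

```
mode coverage (footprint-weighted glycan contact fraction):
  crystallographic    75.0 ± 0.0 %   (planted: 75.0 %)
  parallel            58.3 ± 0.0 %   (planted: 58.3 %)
  upright             21.5 ± 0.0 %   (planted: 21.5 %)

ranking (most shielded first): crystallographic > parallel > upright
```

Five synthetic replicas plant glycan occlusion most heavily on the
canonical-groove residues; the coverage statistic recovers the planted
fractions exactly and ranks the canonical mode as most obstructed and the
upright mode as least — the shielding hierarchy the statistic exists to
resolve. `examples/02–04` demonstrate binding-event detection, interface
areas, and the CSP/titration analysis the same way.

For real data, point the CLI at your own files:

```bash
glycocover coverage --config my_run.yaml --out results/
```

with a YAML config naming the topology (PDB/GRO), replica trajectories
(XTC/DCD), an entity map (which residues are receptor / each glycan /
ligand), and optionally a footprint TSV (`mode, residue_id, weight`).
Subcommands: `simulate`, `coverage`, `contacts`, `surface-map`,
`interface`, `events`, `csp`, `classify`. Outputs are TSV tables with
parameter headers plus a JSON provenance sidecar.

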