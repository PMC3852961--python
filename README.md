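# memorient

Position alpha-helical and beta-barrel transmembrane proteins in an
implicit lipid bilayer using a knowledge-based statistical potential.

The membrane is modelled as an infinite 48 Å slab split into 32 slices
of 1.5 Å along z (z = 0 at the bilayer centre, cytoplasm towards −z).
A potential is trained from pre-oriented structures by counting each
residue's scoring centre (Cβ, Cα for glycine) per slice and converting
the frequencies to log-odds pseudo-energies, with a pseudocount of one
for empty cells.  A structure is positioned by minimising its summed
pseudo-energy over three pose parameters (rotation about x and y,
translation along z) with a genetic algorithm, a Hooke–Jeeves pattern
search, or a grid scan.  On top of that the package provides:

* **Thickness estimation** — the two head-group regions of the potential
  (10 ≤ |z| ≤ 20 Å) are translated independently along z; the offsets
  minimising a split energy yield the hydrophobic thickness
  (30 Å + outward offsets).
* **Decoy discrimination / refinement hooks** — a model ensemble is
  scored with a reduced GA pool, ranked by membrane energy and compared
  against externally supplied TM-scores; the membrane term can be
  combined with an external constraint energy as
  `E_total = E_contact + w·E_membrane` (w in [0.1, 2.0], default 1.6).
* **Synthetic fixtures** — idealized pre-oriented helix bundles with
  controlled residue-depth statistics, so training, orientation,
  thickness and decoy workflows are fully testable offline.

## CLI

```sh
# generate synthetic fixtures (training set / bundle / decoy ensemble)
memorient simulate --what training --seed 1 --out data/train
memorient simulate --what bundle   --seed 2 --out data/bundle

# train a potential from a manifest of pre-oriented structures
memorient train --manifest data/train/manifest.tsv --kind alpha \
    --resolution 3.5 --out alpha.pot

# orient a structure (ga | direct | grid | exhaustive)
memorient orient data/bundle/bundle.pdb --potential alpha.pot \
    --search ga --runs 5 --pop-size 10000 --seed 1 \
    --out oriented.pdb --json result.json

# estimate hydrophobic thickness of an oriented structure
memorient thickness oriented.pdb --potential alpha.pot --step 0.25 \
    --range 8 --json thickness.json

# compare two orientations of the same structure
memorient evaluate oriented.pdb reference.pdb \
    --topology data/bundle/bundle.topo.tsv --tilt-error 3 --z-error 1

# rank a decoy ensemble
memorient rank --manifest decoys/decoys.tsv --potential alpha.pot \
    --native-id native --w 1.6 --seed 1 --json report.json
```

File formats (all plain text): PDB v3.3 structures; potential files
(`#kind/#grid/#resolution` headers plus 20×32 count and energy blocks,
amino acids in alphabetical one-letter order); training manifests
(TSV: `id path chains kind resolution superfamily partners`);
topology (TSV: `chain start end sense`, sense `in-out`/`out-in`);
ensemble manifests (TSV: `model_path e_contact tm_score`).

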