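# ifacecov

Statistical analysis of how well local target–template sequence alignments
cover protein–protein binding sites, and of the structural accuracy of
partial models built from such alignments.

The package provides:

* **Interface extraction** (`ifacecov.interface`) — binding-site residues of a
  two-chain complex by the distance criterion: any atom of a residue strictly
  closer to any atom of the partner chain than the sum of the two van der
  Waals radii plus one water diameter (2.8 Å by default).
* **Alignment metrics** (`ifacecov.alignments`) — per-alignment target
  coverage `q`, interface coverage `q_int`, domain coverage `q_dom`,
  alignment identity/similarity `a_iden`/`a_sim` (BLOSUM62 positives),
  interface-restricted identity/similarity `i_iden`/`i_sim`,
  full-interface-coverage (FIC) classification with a one-missing-residue
  tolerance, and the pool filters (e-value > 1; near-identical
  target/template pairs).
* **Pool statistics** (`ifacecov.stats`) — 5%-bin histograms, per-complex
  FIC summaries (both/one/none of the chains), and the binned FIC probability
  curve with a count-weighted polynomial fit.
* **Model quality** (`ifacecov.quality`) — Kabsch superposition over shared
  Cα atoms, interface RMSD, good (≤ 5 Å) / acceptable (5–10 Å) /
  incorrect (> 10 Å) classes, and top-model (highest identity) /
  best-model (lowest interface RMSD) selection.
* **Synthetic data** (`ifacecov.synthetic`) — seeded generators for two-chain
  complexes with a controllable contact patch, perturbed/truncated models,
  and alignment pools with planted identity bins and FIC probabilities, all
  carrying independent ground truth.
* **Pipeline + CLI** (`ifacecov.pipeline`, `ifacecov.cli`).

Two plain-text fixtures ship with the package: the 329-entry two-chain
complex benchmark list (`data/benchmark_complexes.txt`) and the printed
partial-model results table (`data/top_models.tsv`).

## Command line

```sh
# synthetic two-chain complex + its ground-truth interface
ifacecov synth complex --lengths 30,30 --contact 5 --seed 1 --out-prefix demo

# interface residues of a PDB complex
ifacecov interface --pdb demo.pdb --chains AB --out iface.tsv

# synthetic alignment pool with a planted FIC probability
ifacecov synth pool --n 1000 --p-fic 0.5 --seed 1 --out-prefix pool

# per-alignment metrics (TSV exchange format or BLAST XML)
ifacecov metrics --alignments pool.tsv --out metrics.tsv

# histograms, FIC probability curves and polynomial fits
ifacecov stats --metrics metrics.tsv --qmax 40,100 --fit-degree 3 --out-dir stats

# interface RMSD + quality class for model PDBs against a native complex
ifacecov quality --native native.pdb --native-chains AB --model-chain A \
    --models models/ --interfaces iface.tsv --out quality.tsv

# full pipeline from a JSON config
ifacecov run --config config.json
```

Alignments link to interfaces through the target-id convention
`<complex_id>_<chain_id>`.

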