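# graftsite

Toolkit for identifying stereoselectivity-determining residues in
homologous enzymes and transferring them onto a target enzyme as concrete
variant designs, plus the stereoselectivity and kinetics analytics used to
score those designs.

The pipeline:

1. **`structures`** — PDB reading/cleaning (altloc collapse, MSE→MET,
   water/het filtering, gzip-transparent), catalytic-lysine NZ reference
   lookup, inclusive radius-based active-site region selection, and Kabsch
   least-squares superposition.
2. **`active_site_profile`** — per-atom mean ± SD of the distance to the
   reference atom across a conformational ensemble (multi-model PDB), and
   residue-level aggregation (closest-approach convention).
3. **`homolog_compare`** — mutual-nearest-neighbour Cα correspondence after
   superposition, divergence calls (Δmean vs pooled SD with explicit
   mechanistic exclusions), and sequence-logo information content
   (IC = log₂20 − H) for conservation filtering.
4. **`grafting`** — mapping candidate sites onto a target sequence,
   degenerate-codon expansion (e.g. NDT → 12 amino acids, 0 stops),
   point-variant/motif-swap/deletion design, and residue-disjoint
   combination of variants ("A203G/ΔG204/ΔG205/T18S" naming grammar).
5. **`selectivity`** — signed ee from enantiomer peak areas,
   log(E) = log₁₀[(1+ee)/(1−ee)], replicate statistics, and
   Michaelis–Menten fitting with curvature-based standard errors and
   propagated catalytic efficiency.
6. **`synthetic_data`** — deterministic generators for every input with
   ground truth: homolog structure pairs with planted radial offsets,
   Gaussian-jitter ensembles, column-wise MSA families, peak areas, and
   kinetics data. Each generator draws from an independent seed stream.

## CLI

```sh
graftsite region   --pdb structure.pdb --lys A:167 --radius 6.0
graftsite profile  --ensemble traj.pdb --lys A:167 --radius 6.0 --by-residue --out prof.tsv
graftsite compare  --profile-a a.tsv --profile-b b.tsv --corr corr.tsv \
                   --k 2.0 --min-delta 1.0 --exclude A:45:proton-shuttle
graftsite graft    --target target.fasta --sites sites.tsv --codon NDT \
                   --exclude L20N,L20C --deletions 204,204-205 --out variants.tsv
graftsite ee       --peaks peaks.tsv
graftsite kinetics --data kinetics.tsv
graftsite simulate {pair|ensemble|msa|peaks|kinetics} --seed N --out PATH
```

All file formats are plain text: PDB (optionally gzipped), aligned FASTA,
and TSV tables.

## Notes on conventions

- Region boundary is inclusive (≤ radius); the region is fixed on a
  designated reference conformer, not re-evaluated per frame.
- Distance SDs are sample SDs (n−1).
- The divergence criterion (score ≥ 2 pooled-SD units AND Δ ≥ 1.0 Å) is a
  declared convention with both knobs exposed; mechanistic exclusions are
  always explicit user input.
- log(E) is base-10; |ee| = 1 yields a flagged unbounded sentinel.
- Variant edits are bookkept in original target numbering; deletions
  renumber only the emitted sequence.
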