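# sialofold

Structure-aware annotation toolkit for secreted salivary proteins.
Given predicted protein structures (PDB format, AlphaFold-style pLDDT in
the B-factor column), protein sequences (FASTA) and structural-search hit
tables (Dali-style), it:

- detects **disulfide topologies** from SG–SG distances (< 3 Å by
  default), including inter-chain (dimer) bridges, free cysteines and the
  standard connectivity notations (`C1-C6, C2-C4, C3-C5`,
  `|C:1 C:3 |C:2 C:5`, `A:1|B:8`);
- scans sequences with **PROSITE-syntax motifs** (`ps_scan` semantics)
  and ships built-in zinc-binding, P450 and integrin-triad patterns;
- interprets **structural-search Z scores** (homologous ≥ 20, probably
  homologous 8–20, gray 2–8, not significant < 2) and applies a
  rule-based family-reassignment engine plus a PSSM-model rename ledger;
- nominates **disintegrin candidates**: integrin-binding triads
  (RGD/KGD/KTS/RTS/RED) presented on a cysteine-bridged hairpin
  protruding from the protein body;
- computes **family structural fingerprints**: all-pairs Kabsch RMSD
  statistics over shared secondary-structure residues, with coarse H/E/C
  assignment from Cα geometry;
- reads/writes the **sequence database**: FASTA, TSV/XLSX annotation
  tables, family tabulation and `<identity>-<index>` cluster identifiers.

A `fixtures` module generates every synthetic input the test-suite needs
(engineered cysteine geometries, ideal helices/strands, hairpin and decoy
models, hit tables) deterministically from a seed.

## Test

```sh
python -m pytest tests/
```

One acceptance test (`test_criterion_1_supplementary_counts`) requires
the published supplementary annotation spreadsheet, which is an external
download; place it at `data/supplementary/SupSpreadsheet1.xlsx` (or a TSV
export) or set `TSFAM_SUPPLEMENTARY=/path/to/file`. Without it, that one
test fails with a diagnostic; everything else is self-contained.

## CLI

```sh
sialofold scan seqs.fasta --patterns blocks.prosite --out hits.tsv
sialofold scan seqs.fasta --disintegrin-blocks --out hits.tsv
sialofold ssbond models/ --cutoff 3.0 --out topology.tsv
sialofold classify hits.tsv --motif-hits motif_hits.tsv --out assignments.tsv
sialofold disintegrin seqs.fasta --pdb-dir models/ --out candidates.tsv
sialofold dbstats annotation.tsv --id-column accession --family-column family
sialofold fixtures hairpin --out-dir demo_inputs
```

Numeric knobs live in a plain `key = value` config file (see
`sialofold.cli.RunConfig`); flags override file values, and the effective
config is echoed next to each output.

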