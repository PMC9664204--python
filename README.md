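# wgdkit

WGD-aware comparative genomics of gene-family evolution: a tested pipeline
for simulating genome evolution along a species tree (whole-genome
duplications, tandem duplications, losses, pseudogenizations,
rearrangements), propagating curated evolutionary scenarios into per-species
gene repertoires, reconstructing gains/losses under Dollo parsimony,
LCA gene-tree/species-tree reconciliation with WGD-window timing, and
conserved-synteny / paralogon (quartet) detection.

## Layout

```
src/wgdkit/
  io_formats/        Newick trees, gene tables (BED-like TSV / GFF3 subset),
                     presence matrices, event histories (YAML)
  fixtures/          packaged species tree, curated TRPV event history and
                     presence matrix (plain text)
  synthetic_data.py  genome-evolution simulator with truth log
  scenario_engine.py event-history propagation, counting, nomenclature, diffs
  dollo_inference.py Dollo parsimony gain/loss reconstruction
  reconciliation.py  LCA reconciliation + duplication timing (1R/2R/3R/4R)
  synteny_paralogon.py neighbor windows, synteny comparison, paralogon assembly
  cli.py             `wgdkit` executable
```

## CLI

One executable with subcommands (global flags: `--config`, `--seed`,
`--log-level`, `--out-dir`):

```sh
wgdkit --out-dir out propagate                 # packaged scenario -> counts.tsv
wgdkit --out-dir out dollo                     # packaged matrix  -> dollo.tsv
wgdkit --out-dir out --seed 3 simulate --tree tree.nwk \
       --families 8 --genes-per-chromosome 8 --wgd R=1R --wgd V=2R
wgdkit --out-dir out reconcile --gene-trees out/gene_trees.nwk --tree tree.nwk
wgdkit --out-dir out paralogon --table out/A.genes.tsv --species A --seeds chr1
wgdkit --out-dir out synteny --tables sp1=sp1.tsv --tables sp2=sp2.tsv \
       --family-map map.tsv --focal-family FOCAL
```

`propagate` and `dollo` default to the packaged fixtures when `--tree`,
`--history` or `--matrix` are not given.

## Conventions

- Coordinates are 0-based half-open internally; GFF3 is converted on
  read/write.
- A species-tree branch is identified by its child node's label; the root
  branch is addressable by the root label.
- Pseudogenes are carried with `status=pseudogene`, excluded from gene
  counts unless requested, and treated as *present* by Dollo inference
  (the lineage persists).
- WGD copy naming: 3R copies get `a`/`b` suffixes, 4R copies `α`/`β`;
  lineage-specific serial duplicates use prefix+index (`m`, `sau`, `am`,
  `ch`, `po`, `cy`), with the alias `mTRPV5-2` = `TRPV6`.
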